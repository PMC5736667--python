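"""Survival and competing-risks analysis of the methylation subgroups.

After transplantation, relapse and treatment-related mortality (TRM)
are reciprocal competing risks: Kaplan-Meier answers "is the patient
alive/event-free", the Aalen-Johansen cumulative incidence answers
"what fraction has relapsed by year t given TRM competes", Gray's test
compares those incidence curves across subgroups, and a cause-specific
Cox model quantifies relative relapse risk.
"""

import methylsub as ms

cfg = ms.SimulationConfig(seed=1)
panel, _, _ = ms.generate_reference(cfg)
_, _, _, _, labels = ms.generate_cohort(cfg, panel)
table = ms.generate_outcomes(labels, cfg)

by_group = {g: table[table["methylation_group"] == g]
            for g in ("HM", "IM", "LM")}

print("5-year overall survival (Kaplan-Meier, log-log 95% CI):")
for g, df in by_group.items():
    km = ms.kaplan_meier(df)
    lo, hi = km.ci_at(5.0)
    print(f"  {g}: {km.survival_at(5.0):.2f} ({lo:.2f}-{hi:.2f})")

chi2, dof, p = ms.logrank_test(by_group)
print(f"log-rank across groups: chi2={chi2:.2f}, df={dof}, p={p:.4f}")

print("\n5-year cumulative incidence of relapse (TRM competing):")
for g, df in by_group.items():
    cif = ms.cumulative_incidence(df, cause=1)
    print(f"  {g}: {float(cif(5.0)):.2f}")

gchi2, gdof, gp = ms.grays_test(by_group, cause=1)
print(f"Gray's test on relapse incidence: chi2={gchi2:.2f}, p={gp:.4f}")

cox_tab = table.copy()
cox_tab["hm"] = (cox_tab["methylation_group"] == "HM").astype(int)
cox_tab["im"] = (cox_tab["methylation_group"] == "IM").astype(int)
res = ms.cause_specific_cox(cox_tab, ["hm", "im"], cause=1)
print("\ncause-specific Cox for relapse (reference: LM group):")
print(res.round(3).to_string())
print("-> rr > 1 for the HM indicator reproduces the elevated relapse "
      "hazard planted for the high-methylation subgroup")
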