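"""Train a prospective HM/IM/LM classifier and evaluate it honestly.

Features are the 1,000 most variable subgroup DMPs on CpG islands; the
model is an L1-penalized multinomial logistic regression with its
penalty chosen by 10-fold cross-validation. Evaluation on the held-out
fifth of the cohort uses a permutation-calibrated kappa:
K = (Acc - AccRand) / (1 - AccRand).
"""

import methylsub as ms

cfg = ms.SimulationConfig(seed=1)
panel, annotation, hem_truth = ms.generate_reference(cfg)
beta, _, _, dmp_truth, labels = ms.generate_cohort(cfg, panel)
beta = ms.filter_probes(beta, annotation)

# call subgroup DMPs between the (here: known) groups on nvCpG-like probes
nv = sorted(set(beta.probe_ids) - hem_truth.probe_ids)
nv_beta = beta.select_probes(nv)
ids = {g: labels.index[labels == g] for g in ("HM", "IM", "LM")}
jmml = set()
for a, b in (("HM", "IM"), ("HM", "LM"), ("IM", "LM")):
    res = ms.call_dmps(nv_beta.select_samples(ids[a]),
                       nv_beta.select_samples(ids[b]))
    jmml |= set(res.loc[res["is_dmp"], "probe_id"])
print(f"subgroup DMPs: {len(jmml)}")

features = ms.select_features(
    ms.ProbeSet("jmmlDMPs", frozenset(jmml), ""), annotation, beta, k=1000
)
print(f"classifier features (island DMPs): {len(features)}")

train, test = ms.split_train_test(list(labels.index), labels, seed=1)
feat_beta = beta.select_probes(sorted(features.probe_ids))
model = ms.fit_multinomial_lasso(
    feat_beta.select_samples(train), labels, n_folds=10, seed=1
)
print(f"selected penalty: {model.penalty:.4g}")

probs, pred = ms.predict(model, feat_beta.select_samples(test))
ev = ms.evaluate_kappa(pred.to_numpy(), labels.loc[test].to_numpy(),
                       n_permutations=1000, seed=1)
print(f"held-out accuracy {ev.acc:.3f}, chance accuracy {ev.acc_rand:.3f}, "
      f"kappa {ev.kappa:.3f}")
print("-> kappa near 1 means the subgroups are prospectively predictable")

signature = ms.extract_signature(model)
prec = len(signature.probe_ids & dmp_truth.probe_ids) / len(signature)
print(f"signature probes: {len(signature)}; "
      f"fraction that are truly planted DMPs: {prec:.2f}")
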