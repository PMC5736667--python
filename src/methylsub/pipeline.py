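"""End-to-end orchestration of the subgroup-discovery analysis.

``run_pipeline`` executes the full chain on a synthetic cohort (or, in
principle, any inputs written in the package's formats): simulate ->
probe filtering -> cell-type deconvolution -> hemDMP/nvCpG derivation ->
consensus clustering and HM/IM/LM labeling -> subgroup DMP calling ->
classifier training and permutation-kappa evaluation -> enrichment ->
competing-risks outcome statistics. Every artifact is written to the
output directory together with a JSON manifest recording parameters, the
seed and the SHA-256 of each written file; because every stage is
deterministic given the config, a rerun reproduces identical artifacts
and an identical manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier as clf
from . import consensus as cons
from . import dmp as dm
from . import enrichment as en
from . import outcomes as oc
from . import reference as ref
from . import simulate as sim
from .io import BetaMatrix, ProbeSet, filter_probes

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds and stage parameters of the full analysis."""

    simulation: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    alpha: float = 0.05
    delta_min: float = 0.2
    enrich_alpha: float = 0.01
    snp_bp: int = 5
    blacklist_bp: int = 3
    n_cluster_probes: int = 5000
    k_range: tuple = (2, 3, 4, 5)
    n_iter: int = 500
    subsample_fraction: float = 0.8
    n_markers: int = 500
    n_features: int = 1000
    n_folds: int = 10
    n_lambda: int = 100
    test_fraction: float = 0.2
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1 or not 0 < self.enrich_alpha < 1:
            raise ValueError("alpha thresholds must lie in (0,1)")
        if not 0 <= self.delta_min <= 1:
            raise ValueError("delta_min must lie in [0,1]")
        self.simulation.seed = self.seed


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage in order; returns the run report as a dict."""
    out = Path(outdir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(obj, name: str):
        path = out / name
        path.parent.mkdir(parents=True, exist_ok=True)
        if isinstance(obj, BetaMatrix):
            obj.to_tsv(path)
        elif isinstance(obj, ProbeSet):
            obj.to_text(path)
        elif isinstance(obj, pd.DataFrame):
            obj.to_csv(path, sep="\t" if name.endswith(".tsv") else ",")
        else:
            obj.to_csv(path)
        written.append(path)

    report: dict = {"seed": config.seed}

    # stage 1: simulate
    scfg = config.simulation
    panel, ann, truth_hem = sim.generate_reference(scfg)
    panel_beta, panel_labels = sim.generate_reference_samples(scfg, panel)
    beta, sheet, fractions, truth_dmp, labels = sim.generate_cohort(scfg, panel)
    outcome_tab = sim.generate_outcomes(labels, scfg)
    save(beta, "beta.tsv")
    sheet.to_csv(out / "samples.csv"); written.append(out / "samples.csv")
    ann.to_tsv(out / "annotation.tsv"); written.append(out / "annotation.tsv")
    save(truth_hem, "truth/hem_probes.txt")
    save(truth_dmp, "truth/dmp_probes.txt")
    save(fractions, "truth/cell_fractions.tsv")
    report["n_samples"] = beta.shape[1]
    report["n_probes"] = beta.shape[0]

    # stage 2: probe filtering
    filtered = filter_probes(beta, ann, config.snp_bp, config.blacklist_bp)
    panel_filtered = filter_probes(panel_beta, ann, config.snp_bp, config.blacklist_bp)
    report["n_probes_retained"] = filtered.shape[0]

    # stage 3: deconvolution
    markers = ref.select_marker_probes(panel, config.n_markers)
    est_fracs = ref.deconvolve_cohort(filtered, panel, markers)
    save(est_fracs, "cell_fractions.tsv")
    mae = (est_fracs - fractions[est_fracs.columns]).abs().mean()
    report["deconvolution_mae"] = {k: round(float(v), 4) for k, v in mae.items()}

    # stage 4: hemDMPs / nvCpGs
    hem = dm.derive_hemdmps(
        panel_filtered, panel_labels, alpha=config.alpha, delta_min=config.delta_min
    )
    universe = ProbeSet("filtered_universe", frozenset(filtered.probe_ids), "")
    nv = dm.derive_nvcpgs(universe, hem)
    save(hem, "hemdmps.txt")
    save(nv, "nvcpgs.txt")
    report["n_hemdmps"] = len(hem)
    report["n_nvcpgs"] = len(nv)

    # stage 5: consensus clustering on the most variable nvCpGs
    nv_beta = filtered.select_probes(sorted(nv.probe_ids))
    top = dm.select_most_variable(
        nv_beta, min(config.n_cluster_probes, nv_beta.shape[0])
    )
    cluster_data = filtered.select_probes(sorted(top.probe_ids)).df.T
    result = cons.consensus_cluster(
        cluster_data, config.k_range, config.n_iter,
        config.subsample_fraction, seed=config.seed,
    )
    k = cons.select_k(result)
    assign = result.assignments[k]
    name_map = cons.label_by_methylation(cluster_data, assign, top)
    groups = assign.map(name_map)
    groups.name = "methylation_group"
    save(result.consensus[k], "consensus_k%d.tsv" % k)
    merged = sheet.df.copy()
    merged["methylation_group"] = groups
    merged.to_csv(out / "samples_with_groups.csv")
    written.append(out / "samples_with_groups.csv")
    report["selected_k"] = k
    report["pac"] = {int(kk): round(v, 4) for kk, v in result.pac.items()}
    report["group_sizes"] = groups.value_counts().to_dict()

    # stage 6: subgroup DMPs (union of pairwise calls on nvCpGs)
    group_names = sorted(groups.unique())
    jmml_ids: set = set()
    pair_counts = {}
    for i, a in enumerate(group_names):
        for b in group_names[i + 1:]:
            res = dm.call_dmps(
                nv_beta.select_samples(groups.index[groups == a]),
                nv_beta.select_samples(groups.index[groups == b]),
                alpha=config.alpha, delta_min=config.delta_min,
            )
            hits = set(res.loc[res["is_dmp"], "probe_id"])
            pair_counts[f"{a}_vs_{b}"] = len(hits)
            jmml_ids |= hits
    jmml = ProbeSet(
        "jmmlDMPs", frozenset(jmml_ids),
        "union of pairwise subgroup DMP calls: "
        + ", ".join(f"{k2}={v}" for k2, v in pair_counts.items()),
    )
    save(jmml, "jmmldmps.txt")
    report["n_jmmldmps"] = len(jmml)
    report["jmmldmp_pairs"] = pair_counts

    # stage 7: classifier
    features = clf.select_features(jmml, ann, filtered, k=config.n_features)
    train_ids, test_ids = clf.split_train_test(
        list(groups.index), groups, config.test_fraction, seed=config.seed
    )
    feat_beta = filtered.select_probes(sorted(features.probe_ids))
    model = clf.fit_multinomial_lasso(
        feat_beta.select_samples(train_ids), groups, n_folds=config.n_folds,
        n_lambda=config.n_lambda, seed=config.seed,
    )
    _, pred = clf.predict(model, feat_beta.select_samples(test_ids))
    evaluation = clf.evaluate_kappa(
        pred.to_numpy(), groups.loc[test_ids].to_numpy(),
        n_permutations=config.n_permutations, seed=config.seed,
    )
    signature = clf.extract_signature(model)
    model.to_text(out / "subtype_model.txt"); written.append(out / "subtype_model.txt")
    save(signature, "signature_probes.txt")
    report["classifier"] = {
        "penalty": model.penalty,
        "n_signature": len(signature),
        "acc": round(evaluation.acc, 4),
        "acc_rand": round(evaluation.acc_rand, 4),
        "kappa": round(evaluation.kappa, 4),
    }

    # stage 8: enrichment of subgroup DMPs vs non-DMP nvCpGs
    background = ProbeSet("background", nv.probe_ids - jmml.probe_ids, "")
    cmap = pd.DataFrame(
        {
            "probe_id": list(ann.probe_ids) * 2,
            "category": list(ann.df["cgi_relation"]) + list(ann.df["feature"]),
            "cell_context": ["cgi"] * len(ann.df) + ["feature"] * len(ann.df),
        }
    )
    enr = en.enrich(jmml, background, cmap, alpha=config.enrich_alpha)
    save(enr.set_index("category"), "enrichment.tsv")
    sig = enr[enr["significant"]]
    report["enrichment_hits"] = {
        f"{r.cell_context}:{r.category}": round(r.log2fc, 3)
        for r in sig.itertuples()
    }

    # stage 9: outcome statistics
    # replace the planted labels with the *discovered* groups
    outcome_tab = outcome_tab.drop(columns="methylation_group").join(groups)
    save(outcome_tab, "outcomes.tsv")
    by_group = {
        g: outcome_tab[outcome_tab["methylation_group"] == g]
        for g in group_names
    }
    km5 = {
        g: round(oc.kaplan_meier(t).survival_at(5.0), 4) for g, t in by_group.items()
    }
    chi2, dof, p_lr = oc.logrank_test(by_group)
    gchi2, gdof, p_gray = oc.grays_test(by_group, cause=1)
    cir5 = {
        g: round(float(oc.cumulative_incidence(t, cause=1)(5.0)), 4)
        for g, t in by_group.items()
    }
    cox_tab = outcome_tab.copy()
    for g in group_names:
        if g != "LM":
            cox_tab[f"group_{g}"] = (cox_tab["methylation_group"] == g).astype(int)
    covs = [c for c in cox_tab.columns if c.startswith("group_")]
    try:
        cox = oc.cause_specific_cox(cox_tab, covs, cause=1)
        cox_rr = {c: round(float(cox.loc[c, "rr"]), 3) for c in covs}
    except RuntimeError as exc:
        cox_rr = {"error": str(exc)}
    report["outcomes"] = {
        "km_5y": km5,
        "logrank_p": round(p_lr, 5),
        "cir_5y": cir5,
        "grays_p": round(p_gray, 5),
        "cox_rr_relapse": cox_rr,
    }

    manifest = {
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "files": {str(p.relative_to(out)): _sha256(p) for p in sorted(written)},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    logger.info("pipeline complete: %s", report)
    return report
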