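"""Differentially methylated probe (DMP) calling.

A probe is a DMP between two sample groups when it passes both a
statistical and an effect-size threshold: Benjamini-Hochberg adjusted
Welch-t p-value < alpha (default 0.05) and absolute methylation
difference |delta| = |mean_b - mean_a| >= delta_min (default 0.2 beta
units). The same caller serves three roles in the pipeline:

* hemDMPs — probes dynamic in normal hematopoietic differentiation,
  the union of HSC-vs-mature-cell-type calls over six mature types;
* jmmlDMPs — probes separating the discovered methylation subgroups,
  called on the nvCpG complement of the hemDMPs;
* genotype-specific DMPs — one genotype group against all others.

Degenerate constant probes are handled with a variance floor of 1e-12
(they get t = 0, p = 1); probes with fewer than two non-missing values
in either group are untestable and are excluded with a count, never
silently dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import BetaMatrix, ProbeSet, SampleSheet, ValidationError

VAR_FLOOR = 1e-12

#: mature cell types compared against HSC when deriving hemDMPs
MATURE_TYPES = ("granulocyte", "monocyte", "NK", "CD8T", "CD4T", "B")


def welch_test(a: np.ndarray, b: np.ndarray):
    """Row-wise two-sided unpaired Welch's t-test.

    Parameters
    ----------
    a, b
        Arrays of shape (probes, samples); NaN entries are missing.

    Returns
    -------
    DataFrame with columns ``mean_a, mean_b, n_a, n_b, t_stat, df, p,
    testable``. Untestable probes (< 2 non-missing values in either
    group) carry NaN statistics and ``testable=False``.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    n_a = np.sum(~np.isnan(a), axis=1)
    n_b = np.sum(~np.isnan(b), axis=1)
    testable = (n_a >= 2) & (n_b >= 2)

    import warnings as _warnings

    with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
        # untestable rows (n < 2) legitimately produce all-NaN slices
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean_a = np.nanmean(a, axis=1)
        mean_b = np.nanmean(b, axis=1)
        var_a = np.nanvar(a, axis=1, ddof=1)
        var_b = np.nanvar(b, axis=1, ddof=1)
    var_a = np.maximum(var_a, VAR_FLOOR)
    var_b = np.maximum(var_b, VAR_FLOOR)

    with np.errstate(invalid="ignore", divide="ignore"):
        se2_a = var_a / n_a
        se2_b = var_b / n_b
        se = np.sqrt(se2_a + se2_b)
        t = (mean_b - mean_a) / se
        # Satterthwaite degrees of freedom
        df = (se2_a + se2_b) ** 2 / (
            se2_a**2 / (n_a - 1) + se2_b**2 / (n_b - 1)
        )
        p = 2.0 * stats.t.sf(np.abs(t), df)
    t = np.where(testable, t, np.nan)
    p = np.where(testable, np.minimum(p, 1.0), np.nan)
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "n_a": n_a,
            "n_b": n_b,
            "t_stat": t,
            "df": np.where(testable, df, np.nan),
            "p": p,
            "testable": testable,
        }
    )


def benjamini_hochberg(p) -> np.ndarray:
    """Step-up BH adjusted p-values (monotone in rank, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValidationError("NaN p-values passed to benjamini_hochberg")
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values outside [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def call_dmps(
    a: BetaMatrix,
    b: BetaMatrix,
    alpha: float = 0.05,
    delta_min: float = 0.2,
) -> pd.DataFrame:
    """Call DMPs between two disjoint sample groups on shared probes.

    Returns one row per testable probe, ordered by probe_id, with
    ``delta = mean_b - mean_a`` and ``is_dmp = (p_adj < alpha) &
    (|delta| >= delta_min)``. BH correction is applied across the
    testable probes of this comparison only.
    """
    overlap = set(a.sample_ids) & set(b.sample_ids)
    if overlap:
        raise ValidationError(f"sample groups overlap: {sorted(overlap)[:5]}")
    if not a.probe_ids.equals(b.probe_ids):
        common = a.probe_ids.intersection(b.probe_ids)
        if len(common) == 0:
            raise ValidationError("no shared probes between groups")
        a, b = a.select_probes(common), b.select_probes(common)
    res = welch_test(a.values, b.values)
    res.insert(0, "probe_id", a.probe_ids.to_numpy())
    n_untestable = int((~res["testable"]).sum())
    res = res[res["testable"]].drop(columns="testable").copy()
    res["delta"] = res["mean_b"] - res["mean_a"]
    res["p_adj"] = benjamini_hochberg(res["p"].to_numpy()) if len(res) else []
    res["is_dmp"] = (res["p_adj"] < alpha) & (res["delta"].abs() >= delta_min)
    res = res.sort_values("probe_id", kind="mergesort").reset_index(drop=True)
    res.attrs["n_untestable"] = n_untestable
    res.attrs["alpha"] = alpha
    res.attrs["delta_min"] = delta_min
    return res


def derive_hemdmps(
    panel_samples: BetaMatrix,
    labels: pd.Series,
    alpha: float = 0.05,
    delta_min: float = 0.2,
) -> ProbeSet:
    """Union of HSC-vs-mature DMP calls over the six mature cell types.

    *labels* maps sample id -> cell type and must include ``HSC`` plus
    granulocyte, monocyte, NK, CD8T, CD4T and B samples.
    """
    labels = pd.Series(labels)
    present = set(labels.unique())
    needed = {"HSC", *MATURE_TYPES}
    if not needed <= present:
        raise ValidationError(f"missing cell-type labels: {sorted(needed - present)}")
    hsc = panel_samples.select_samples(labels.index[labels == "HSC"])
    union: set = set()
    prov = [f"hemDMPs: HSC vs mature, alpha={alpha}, delta_min={delta_min}"]
    for ct in MATURE_TYPES:
        grp = panel_samples.select_samples(labels.index[labels == ct])
        res = call_dmps(hsc, grp, alpha=alpha, delta_min=delta_min)
        hits = res.loc[res["is_dmp"], "probe_id"]
        union.update(hits)
        prov.append(f"HSC vs {ct}: {len(hits)} DMPs")
    prov.append(f"union: {len(union)} probes")
    return ProbeSet("hemDMPs", frozenset(union), "\n".join(prov))


def derive_nvcpgs(universe: ProbeSet, hem: ProbeSet) -> ProbeSet:
    """Complement of the hemDMPs within the probe universe (the nvCpGs)."""
    if not hem.probe_ids <= universe.probe_ids:
        extra = sorted(hem.probe_ids - universe.probe_ids)[:5]
        raise ValidationError(f"hemDMPs not a subset of universe (e.g. {extra})")
    return ProbeSet(
        "nvCpGs",
        universe.probe_ids - hem.probe_ids,
        f"complement of {hem.name} ({len(hem)}) in {universe.name} ({len(universe)})",
    )


def select_most_variable(beta: BetaMatrix, k: int) -> ProbeSet:
    """Top-k probes by sample standard deviation (ddof=1, NaN ignored).

    Ties are broken lexicographically by probe id so the selection is
    fully deterministic.
    """
    if k <= 0:
        raise ValidationError("k must be positive")
    if k > beta.shape[0]:
        raise ValidationError(f"k={k} exceeds {beta.shape[0]} probes")
    sd = pd.Series(np.nanstd(beta.values, axis=1, ddof=1), index=beta.probe_ids)
    order = sd.sort_index().sort_values(ascending=False, kind="mergesort")
    top = order.index[:k]
    return ProbeSet(
        f"top{k}_variable", frozenset(top), f"top {k} probes by sd across samples"
    )


def genotype_specific_dmps(
    beta: BetaMatrix,
    samples: SampleSheet,
    genotype: str,
    alpha: float = 0.05,
    delta_min: float = 0.2,
) -> ProbeSet:
    """DMPs of one genotype group versus all other samples."""
    geno = samples.df["genotype"]
    if genotype not in set(geno.dropna()):
        raise ValidationError(f"unknown genotype label {genotype!r}")
    in_ids = geno.index[geno == genotype]
    out_ids = geno.index[(geno != genotype) & geno.notna()]
    if len(in_ids) < 2 or len(out_ids) < 2:
        raise ValidationError("need >= 2 samples inside and outside the genotype group")
    res = call_dmps(
        beta.select_samples(in_ids), beta.select_samples(out_ids),
        alpha=alpha, delta_min=delta_min,
    )
    hits = frozenset(res.loc[res["is_dmp"], "probe_id"])
    return ProbeSet(
        f"{genotype}_DMPs",
        hits,
        f"{genotype} (n={len(in_ids)}) vs rest (n={len(out_ids)}), "
        f"alpha={alpha}, delta_min={delta_min}",
    )
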