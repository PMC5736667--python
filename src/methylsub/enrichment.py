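"""Foreground/background enrichment statistics for probe and gene sets.

For each annotation category (genomic feature, chromatin meta-state in a
cell context, CGI relation, ...), the effect size is log2(OF/OB), where
OF is the fraction of foreground probes in the category and OB the same
fraction for the background. Significance comes from a two-sided Fisher
exact test on the 2x2 table (in/out category x foreground/background),
with Benjamini-Hochberg correction across the categories of each cell
context and a significance threshold of 0.01 on the adjusted p.

Gene-set enrichment of hit genes against a gene universe uses the
one-sided hypergeometric tail, again BH-corrected across sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dmp import benjamini_hochberg
from .io import ProbeSet, ValidationError

ENRICH_ALPHA = 0.01


@dataclass
class EnrichmentResult:
    category: str
    cell_context: str | None
    of: float
    ob: float
    log2fc: float
    p: float
    p_adj: float
    significant: bool


def _log2fc(of: float, ob: float) -> float:
    if of > 0 and ob > 0:
        return float(np.log2(of / ob))
    if of == 0 and ob == 0:
        return 0.0
    return float(np.inf if ob == 0 else -np.inf)


def enrich(
    foreground: ProbeSet,
    background: ProbeSet,
    category_map: pd.DataFrame,
    alpha: float = ENRICH_ALPHA,
) -> pd.DataFrame:
    """Per-category Fisher enrichment of foreground vs background probes.

    *category_map* has columns ``probe_id, category`` and optionally
    ``cell_context``; it must cover every probe of both sets (probes may
    carry several categories, one row each). BH correction is applied
    within each cell context.
    """
    if foreground.probe_ids & background.probe_ids:
        raise ValidationError("foreground and background overlap")
    cmap = category_map.copy()
    if "cell_context" not in cmap.columns:
        cmap["cell_context"] = None
    covered = set(cmap["probe_id"])
    uncovered = (foreground.probe_ids | background.probe_ids) - covered
    if uncovered:
        raise ValidationError(
            f"{len(uncovered)} probes missing from category map "
            f"(e.g. {sorted(uncovered)[:3]})"
        )
    n_f, n_b = len(foreground), len(background)
    fore, back = foreground.probe_ids, background.probe_ids

    rows = []
    for ctx, sub in cmap.groupby("cell_context", dropna=False, sort=True):
        ctx_rows = []
        for cat, catsub in sub.groupby("category", sort=True):
            probes = set(catsub["probe_id"])
            f_in = len(probes & fore)
            b_in = len(probes & back)
            of, ob = f_in / n_f, b_in / n_b
            table = [[f_in, n_f - f_in], [b_in, n_b - b_in]]
            _, p = stats.fisher_exact(table, alternative="two-sided")
            ctx_rows.append(
                {
                    "category": cat,
                    "cell_context": None if pd.isna(ctx) else ctx,
                    "of": of,
                    "ob": ob,
                    "log2fc": _log2fc(of, ob),
                    "p": p,
                }
            )
        padj = benjamini_hochberg([r["p"] for r in ctx_rows])
        for r, pa in zip(ctx_rows, padj):
            r["p_adj"] = pa
            r["significant"] = bool(pa < alpha)
        rows.extend(ctx_rows)
    return pd.DataFrame(rows)


def gene_set_test(
    hit_genes: set, universe_genes: set, gene_sets: dict
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    P(X >= k) with population = universe, successes = set members in the
    universe, draws = hits. Results are BH-corrected across sets and
    ranked by p.
    """
    hit_genes, universe_genes = set(hit_genes), set(universe_genes)
    if not universe_genes:
        raise ValidationError("empty gene universe")
    if not hit_genes <= universe_genes:
        raise ValidationError("hit genes must be a subset of the universe")
    M, N = len(universe_genes), len(hit_genes)
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe_genes
        k = len(members & hit_genes)
        n = len(members)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        rows.append({"gene_set": name, "n_set": n, "n_hit": k, "p": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
    return out.sort_values(["p", "gene_set"], kind="mergesort").reset_index(drop=True)
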