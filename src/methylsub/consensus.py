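"""Resampling-based consensus clustering for methylation subgroup discovery.

Hierarchical clustering uses Manhattan (city-block) distances with
Ward's linkage in its distance-squared update form (scipy's ``ward``
Lance-Williams recurrence applied to a precomputed distance matrix,
equivalent to R hclust's ``ward.D2``). Consensus clustering repeats the
clustering on random 80% subsamples of the cohort; the consensus matrix
records, for every sample pair, the fraction of co-sampled iterations in
which the pair landed in the same cluster. Cluster-number selection uses
the PAC score (proportion of ambiguous clustering): the fraction of
off-diagonal consensus entries strictly between 0.1 and 0.9 — lower is
more stable. Discovered clusters are named HM / IM / LM by ranking their
mean methylation over the clustering probes, descending.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .io import ProbeSet, ValidationError

logger = logging.getLogger(__name__)

PAC_LOWER, PAC_UPPER = 0.1, 0.9


@dataclass
class ConsensusResult:
    """Consensus matrices, assignments and PAC scores per candidate k."""

    k_values: list
    consensus: dict = field(repr=False)  # k -> sample x sample DataFrame
    assignments: dict = field(repr=False)  # k -> pd.Series sample -> label
    pac: dict
    n_iter: int
    subsample_fraction: float
    seed: int


def _impute_median(data: np.ndarray) -> np.ndarray:
    """Replace missing entries by the per-probe (column) median."""
    if not np.isnan(data).any():
        return data
    med = np.nanmedian(data, axis=0)
    out = data.copy()
    idx = np.where(np.isnan(out))
    out[idx] = np.take(med, idx[1])
    logger.info("imputed %d missing cells by probe median", len(idx[0]))
    return out


def hierarchical_cluster(data: np.ndarray, k: int) -> np.ndarray:
    """Cluster samples (rows) at k via Manhattan distance + Ward linkage.

    Labels are integers 1..k renumbered by first occurrence in input
    order, so the output is deterministic given the input row order.
    """
    data = np.asarray(data, dtype=float)
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > data.shape[0]:
        raise ValidationError(f"k={k} exceeds {data.shape[0]} samples")
    data = _impute_median(data)
    if k == 1:
        return np.ones(data.shape[0], dtype=int)
    Z = linkage(pdist(data, metric="cityblock"), method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    return _renumber(raw)


def _renumber(labels: np.ndarray) -> np.ndarray:
    order: dict = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order) + 1
        out[i] = order[lab]
    return out


def consensus_cluster(
    data,
    k_range=(2, 3, 4, 5),
    n_iter: int = 500,
    subsample_fraction: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Subsampled consensus clustering over a range of cluster numbers.

    *data* is a sample x probe matrix (DataFrame or array). Per
    iteration, ceil(fraction * n) samples are drawn without replacement
    and clustered at each k; consensus(i, j) = co-cluster count /
    co-sample count. Pairs never co-sampled get consensus 0 with a
    warning. Final assignments at each k come from hierarchical
    clustering of 1 - consensus.
    """
    if isinstance(data, pd.DataFrame):
        sample_ids = data.index
        X = data.to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        sample_ids = pd.RangeIndex(X.shape[0])
    n = X.shape[0]
    k_range = sorted(set(int(k) for k in k_range))
    if any(k < 2 or k > n - 1 for k in k_range):
        raise ValidationError(f"k_range must lie within [2, {n - 1}]")
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    if not 0 < subsample_fraction <= 1:
        raise ValidationError("subsample_fraction must be in (0, 1]")
    X = _impute_median(X)
    rng = np.random.default_rng(seed)
    m = int(np.ceil(subsample_fraction * n))

    co_cluster = {k: np.zeros((n, n)) for k in k_range}
    co_sample = np.zeros((n, n))
    for _ in range(n_iter):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        co_sample[np.ix_(idx, idx)] += 1
        sub = X[idx]
        Z = linkage(pdist(sub, metric="cityblock"), method="ward")
        for k in k_range:
            labs = fcluster(Z, t=k, criterion="maxclust")
            same = labs[:, None] == labs[None, :]
            co_cluster[k][np.ix_(idx, idx)] += same

    never = (co_sample == 0) & ~np.eye(n, dtype=bool)
    if never.any():
        logger.warning(
            "%d sample pairs never co-sampled; their consensus is 0",
            int(never.sum() // 2),
        )
    denom = np.where(co_sample > 0, co_sample, 1.0)

    consensus, assignments, pac = {}, {}, {}
    iu = np.triu_indices(n, k=1)
    for k in k_range:
        M = co_cluster[k] / denom
        np.fill_diagonal(M, 1.0)
        M = (M + M.T) / 2
        off = M[iu]
        pac[k] = float(np.mean((off > PAC_LOWER) & (off < PAC_UPPER)))
        Zc = linkage(squareform(1.0 - M, checks=False), method="ward")
        labs = _renumber(fcluster(Zc, t=k, criterion="maxclust"))
        consensus[k] = pd.DataFrame(M, index=sample_ids, columns=sample_ids)
        assignments[k] = pd.Series(labs, index=sample_ids, name=f"k{k}")
    return ConsensusResult(
        k_values=k_range,
        consensus=consensus,
        assignments=assignments,
        pac=pac,
        n_iter=n_iter,
        subsample_fraction=subsample_fraction,
        seed=seed,
    )


def select_k(result: ConsensusResult) -> int:
    """The k minimizing PAC; ties resolved toward the smallest k."""
    if len(result.k_values) < 2:
        raise ValidationError("need >= 2 candidate values of k")
    return min(result.k_values, key=lambda k: (result.pac[k], k))


def label_by_methylation(
    data, labels: pd.Series, probes: ProbeSet | None = None
) -> dict:
    """Name 2 or 3 clusters HM / (IM) / LM by mean beta, descending.

    *data* is sample x probe (DataFrame with probe columns when *probes*
    is given). Returns a map cluster id -> group name; invariant to how
    the cluster ids are numbered.
    """
    labels = pd.Series(labels)
    clusters = sorted(labels.unique())
    if len(clusters) not in (2, 3):
        raise ValidationError(
            f"{len(clusters)} clusters: HM/IM/LM nomenclature is defined "
            "for 2 or 3 only"
        )
    if isinstance(data, pd.DataFrame):
        sub = data[sorted(probes.probe_ids)] if probes is not None else data
        vals = sub.to_numpy(dtype=float)
    else:
        vals = np.asarray(data, dtype=float)
    means = {
        c: float(np.nanmean(vals[(labels == c).to_numpy()])) for c in clusters
    }
    ranked = sorted(clusters, key=lambda c: -means[c])
    names = ["HM", "IM", "LM"] if len(clusters) == 3 else ["HM", "LM"]
    return dict(zip(ranked, names))
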