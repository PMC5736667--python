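"""Mapping samples onto the normal-hematopoiesis methylation landscape.

Two complementary views:

* a PCA of methylation dynamics across normal hematopoiesis, trained on
  reference cell populations (probe variance ranked across the six HSPC
  populations only) with leukemia samples projected as supplementary
  points — they receive coordinates but never influence the fit;
* reference-based cell-type deconvolution: constrained least squares of
  a sample's betas against the 12 reference profiles over a marker probe
  set, with fractions >= 0 and sum <= 1 (the slack absorbs any
  unexplained component), the classical constrained-projection approach
  to methylome cell-composition inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .io import BetaMatrix, ProbeSet, ValidationError
from .simulate import HSPC_TYPES, ReferencePanel


@dataclass
class PcaModel:
    """PCA of reference methylomes over the top-k HSPC-variable probes."""

    probe_ids: list
    center: np.ndarray = field(repr=False)
    loadings: np.ndarray = field(repr=False)  # probes x components
    explained_variance: np.ndarray = field(repr=False)
    explained_variance_ratio: np.ndarray = field(repr=False)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class CellFractions:
    """Estimated cell-type composition of one sample."""

    sample_id: str
    fractions: dict
    residual_norm: float

    def __post_init__(self):
        total = sum(self.fractions.values())
        if any(f < -1e-8 for f in self.fractions.values()) or total > 1 + 1e-6:
            raise ValidationError(
                f"invalid fractions for {self.sample_id}: sum={total:.6f}"
            )


def fit_reference_pca(
    reference_samples: BetaMatrix,
    labels: pd.Series,
    top_k: int = 5000,
    n_components: int = 5,
) -> PcaModel:
    """Fit PCA on normal cell types over the top-k HSPC-variable probes.

    Probe variance is ranked only across samples of the six HSPC
    populations (HSC, MPP, L-MPP, CMP, GMP, MEP); the PCA itself is then
    fitted on *all* reference samples restricted to those probes, on
    centered unscaled betas. Loading signs are fixed by forcing the
    largest-magnitude entry of each loading positive.
    """
    labels = pd.Series(labels)
    hspc_ids = labels.index[labels.isin(HSPC_TYPES)]
    if len(hspc_ids) < 2:
        raise ValidationError("need >= 2 HSPC reference samples")
    if top_k > reference_samples.shape[0]:
        raise ValidationError(
            f"top_k={top_k} exceeds {reference_samples.shape[0]} probes"
        )
    hspc = reference_samples.select_samples(hspc_ids)
    sd = pd.Series(
        np.nanstd(hspc.values, axis=1, ddof=1), index=reference_samples.probe_ids
    )
    if np.all(sd.to_numpy() == 0):
        raise ValidationError("zero variance across all probes in HSPC samples")
    order = sd.sort_index().sort_values(ascending=False, kind="mergesort")
    probes = list(order.index[:top_k])

    X = reference_samples.select_probes(probes).values.T  # samples x probes
    n_comp = min(n_components, X.shape[0] - 1, X.shape[1])
    center = X.mean(axis=0)
    Xc = X - center
    # thin SVD on centered betas (covariance PCA, unscaled)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = vt[:n_comp].T
    ev = s[:n_comp] ** 2 / (X.shape[0] - 1)
    total_var = np.sum(s**2) / (X.shape[0] - 1)
    # deterministic sign: largest-|.| entry of each loading positive
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    return PcaModel(
        probe_ids=probes,
        center=center,
        loadings=loadings,
        explained_variance=ev,
        explained_variance_ratio=ev / total_var if total_var > 0 else ev * 0,
    )


def project_supplementary(model: PcaModel, samples: BetaMatrix) -> pd.DataFrame:
    """Project samples into the reference PCA space without refitting.

    coordinates = (beta - center) @ loadings; every model probe must be
    present in the input.
    """
    missing = [p for p in model.probe_ids if p not in samples.probe_ids]
    if missing:
        raise ValidationError(
            f"{len(missing)} model probes missing from input (e.g. {missing[:5]})"
        )
    X = samples.select_probes(model.probe_ids).values.T
    coords = (X - model.center) @ model.loadings
    return pd.DataFrame(
        coords,
        index=samples.sample_ids,
        columns=[f"PC{i + 1}" for i in range(model.n_components)],
    )


def select_marker_probes(panel: ReferencePanel, m: int = 500) -> ProbeSet:
    """Top-m probes by across-cell-type variance in the reference panel."""
    var = panel.profiles.var(axis=0, ddof=1)
    order = var.sort_index().sort_values(ascending=False, kind="mergesort")
    return ProbeSet(
        f"markers_top{m}",
        frozenset(order.index[:m]),
        f"top {m} probes by variance across the 12 reference cell types",
    )


def _solve_fractions(A: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """min ||A f - y||^2  s.t.  f >= 0, sum(f) <= 1 (quadratic program)."""
    k = A.shape[1]
    AtA = A.T @ A
    Aty = A.T @ y

    def obj(f):
        r = A @ f - y
        return 0.5 * float(r @ r)

    def grad(f):
        return AtA @ f - Aty

    cons = [{"type": "ineq", "fun": lambda f: 1.0 - f.sum(),
             "jac": lambda f: -np.ones(k)}]
    x0 = np.full(k, 1.0 / (k + 1))
    res = optimize.minimize(
        obj, x0, jac=grad, bounds=[(0.0, 1.0)] * k, constraints=cons,
        method="SLSQP", options={"maxiter": 500, "ftol": 1e-14},
    )
    if not res.success:  # pragma: no cover - SLSQP rarely fails on this QP
        raise RuntimeError(f"deconvolution QP failed: {res.message}")
    f = np.clip(res.x, 0.0, None)
    if f.sum() > 1.0:
        f = f / f.sum()
    return f, float(np.linalg.norm(A @ f - y))


def estimate_cell_fractions(
    sample_beta: pd.Series | np.ndarray,
    panel: ReferencePanel,
    marker_probes: ProbeSet,
    sample_id: str = "sample",
) -> CellFractions:
    """Constrained-projection deconvolution of one sample.

    Solves least squares of the sample's marker betas against the
    reference profiles under fractions >= 0 and sum <= 1. The marker
    design must have full column rank (collinear cell types are reported).
    """
    markers = sorted(marker_probes.probe_ids)
    if not set(markers) <= set(panel.probe_ids):
        raise ValidationError("marker probes not all present in the reference panel")
    if len(markers) < len(panel.cell_types):
        raise ValidationError(
            f"need >= {len(panel.cell_types)} marker probes, got {len(markers)}"
        )
    A = panel.profiles[markers].to_numpy().T  # markers x cell types
    if np.linalg.matrix_rank(A) < A.shape[1]:
        corr = np.corrcoef(A.T)
        pairs = [
            (panel.cell_types[i], panel.cell_types[j])
            for i in range(len(panel.cell_types))
            for j in range(i + 1, len(panel.cell_types))
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValidationError(
            f"rank-deficient marker design; collinear cell types: {pairs}"
        )
    if isinstance(sample_beta, pd.Series):
        y = sample_beta.loc[markers].to_numpy(dtype=float)
    else:
        y = np.asarray(sample_beta, dtype=float)
        if y.shape[0] != len(markers):
            raise ValidationError("sample vector length != number of markers")
    f, resid = _solve_fractions(A, y)
    return CellFractions(
        sample_id, dict(zip(panel.cell_types, f)), residual_norm=resid
    )


def deconvolve_cohort(
    beta: BetaMatrix, panel: ReferencePanel, marker_probes: ProbeSet
) -> pd.DataFrame:
    """Estimate cell fractions for every sample; rows = samples."""
    markers = sorted(set(marker_probes.probe_ids) & set(beta.probe_ids))
    ps = ProbeSet(marker_probes.name, frozenset(markers), marker_probes.provenance)
    sub = beta.select_probes(markers)
    rows = {}
    for sid in sub.sample_ids:
        cf = estimate_cell_fractions(sub.df[sid], panel, ps, sample_id=sid)
        rows[sid] = cf.fractions
    out = pd.DataFrame.from_dict(rows, orient="index")[list(panel.cell_types)]
    out.index.name = "sample_id"
    return out
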