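"""Seeded synthetic cohort generator.

Emulates the data structure of a 450K-array study of juvenile
myelomonocytic leukemia (JMML): a reference panel of 12 hematopoietic
cell-type methylomes containing differentiation-dynamic CpGs, leukemia
samples formed as Dirichlet cell-type mixtures of those references, three
planted methylation subgroups (HM / IM / LM) whose effects are
CGI-biased and overwhelmingly hypermethylating, genotype and karyotype
labels correlated with subgroup, and relapse / treatment-related
mortality (TRM) competing-risk outcomes.

All randomness derives from one integer seed through a hierarchical
``numpy.random.SeedSequence`` stream per stage (reference, panel
replicates, cohort, outcomes), so stages can be regenerated
independently and the whole cohort is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import BetaMatrix, ProbeAnnotation, ProbeSet, SampleSheet, ValidationError

CELL_TYPES = (
    "HSC", "MPP", "L-MPP", "CMP", "GMP", "MEP",
    "granulocyte", "monocyte", "NK", "CD4T", "CD8T", "B",
)
HSPC_TYPES = ("HSC", "MPP", "L-MPP", "CMP", "GMP", "MEP")
MATURE_TYPES = ("granulocyte", "monocyte", "NK", "CD8T", "CD4T", "B")

# myeloid-weighted mixture concentrations: JMML is a myeloproliferative
# disorder, so granulocytes/monocytes dominate, with variable HSPC and
# B-cell admixture
_DEFAULT_DIRICHLET = {
    "HSC": 1.0, "MPP": 0.6, "L-MPP": 0.5, "CMP": 1.0, "GMP": 1.0, "MEP": 0.6,
    "granulocyte": 6.0, "monocyte": 3.5, "NK": 0.5, "CD4T": 1.2, "CD8T": 1.0,
    "B": 1.6,
}

# subgroup-conditional genotype frequencies echoing the enrichments seen
# in JMML cohorts (HM: somatic PTPN11; IM: KRAS with monosomy 7;
# LM: NRAS / CBL / Noonan)
_GENOTYPE_PROBS = {
    "HM": {"PTPN11": 0.62, "KRAS": 0.06, "NRAS": 0.08, "CBL": 0.02,
           "NF1": 0.10, "Noonan": 0.02, "quintuple_negative": 0.10},
    "IM": {"PTPN11": 0.25, "KRAS": 0.38, "NRAS": 0.10, "CBL": 0.05,
           "NF1": 0.12, "Noonan": 0.02, "quintuple_negative": 0.08},
    "LM": {"PTPN11": 0.08, "KRAS": 0.04, "NRAS": 0.28, "CBL": 0.25,
           "NF1": 0.05, "Noonan": 0.25, "quintuple_negative": 0.05},
}
_KARYOTYPE_PROBS = {
    "HM": {"normal": 0.80, "monosomy7": 0.08, "other": 0.12},
    "IM": {"normal": 0.35, "monosomy7": 0.55, "other": 0.10},
    "LM": {"normal": 0.88, "monosomy7": 0.04, "other": 0.08},
}
_PLATELETS_LOW = {"HM": 0.78, "IM": 0.55, "LM": 0.29}
_HBF_ELEVATED = {"HM": 0.95, "IM": 0.60, "LM": 0.29}

_EPS = 1e-3  # beta clipping bound before logit


@dataclass
class SimulationConfig:
    """Stated-world parameters of the synthetic cohort.

    Defaults reproduce the recovery-experiment conditions the pipeline is
    validated under: 20,000 probes, ~16% differentiation-dynamic CpGs,
    2% of the remaining probes carrying planted subgroup effects
    (delta_hm=0.25, delta_im=0.12 beta units vs LM, 80% on CpG islands,
    98% hypermethylating), 20 samples per subgroup, logit-scale noise
    sd 0.05, and per-group cause-specific hazards (per year) giving the
    HM group a markedly higher relapse incidence.
    """

    n_probes: int = 20_000
    frac_hem_dynamic: float = 0.16
    frac_subgroup_dmp: float = 0.02
    delta_hm: float = 0.25
    delta_im: float = 0.12
    delta_hem: float = 0.3
    cgi_bias: float = 0.8
    hyper_fraction: float = 0.98
    noise_sd: float = 0.05
    n_per_group: int = 20
    n_replicates: int = 10
    mixture_dirichlet: dict = field(default_factory=lambda: dict(_DEFAULT_DIRICHLET))
    outcome_hazards: dict = field(
        default_factory=lambda: {
            "HM": (0.18, 0.06), "IM": (0.10, 0.06), "LM": (0.03, 0.05)
        }
    )
    censor_rate: float = 0.08
    frac_snp_near: float = 0.01
    frac_sex: float = 0.01
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_hem_dynamic", "frac_subgroup_dmp", "cgi_bias",
                     "hyper_fraction", "frac_snp_near", "frac_sex"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name}={v} outside [0,1]")
        if not self.delta_hm > self.delta_im >= 0:
            raise ValidationError("require delta_hm > delta_im >= 0")
        for g, (h1, h2) in self.outcome_hazards.items():
            if h1 < 0 or h2 < 0:
                raise ValidationError(f"negative hazard for group {g}")
        if self.noise_sd < 0 or self.censor_rate < 0:
            raise ValidationError("noise_sd and censor_rate must be >= 0")

    def seed_sequence(self, stage: int) -> np.random.SeedSequence:
        return np.random.SeedSequence([int(self.seed), stage])


@dataclass
class ReferencePanel:
    """Mean methylomes of the 12 hematopoietic cell types.

    ``profiles`` is cell_type x probe. The generator attaches the probe
    annotation and the planted differentiation-dynamic probe set so the
    panel is self-contained for downstream mixing and deconvolution.
    """

    cell_types: tuple
    profiles: pd.DataFrame = field(repr=False)
    annotation: ProbeAnnotation | None = None
    hem_truth: ProbeSet | None = None

    def __post_init__(self):
        if len(self.cell_types) != 12:
            raise ValidationError("reference panel must have 12 cell types")
        vals = self.profiles.to_numpy()
        if np.any((vals < 0) | (vals > 1)):
            raise ValidationError("reference profiles outside [0,1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.profiles.columns


def _make_annotation(config: SimulationConfig, rng: np.random.Generator) -> ProbeAnnotation:
    n = config.n_probes
    probe_ids = np.array([f"cg{i:08d}" for i in range(n)])
    rel = rng.choice(
        ["island", "shore", "shelf", "open_sea"], size=n, p=[0.30, 0.25, 0.10, 0.35]
    )
    feature = rng.choice(
        ["promoter", "utr5", "exon", "intron", "utr3", "intergenic", "ncRNA", "repeat"],
        size=n, p=[0.25, 0.05, 0.15, 0.30, 0.05, 0.13, 0.04, 0.03],
    )
    chrom = np.array([f"chr{c}" for c in rng.integers(1, 23, size=n)], dtype=object)
    n_sex = int(round(config.frac_sex * n))
    if n_sex:
        sex_idx = rng.choice(n, size=n_sex, replace=False)
        chrom[sex_idx] = rng.choice(["chrX", "chrY"], size=n_sex)
    pos = np.sort(rng.integers(1, 2_000_000_00, size=n))
    snp_distance = np.full(n, np.nan)
    n_snp = int(round(config.frac_snp_near * n))
    if n_snp:
        snp_idx = rng.choice(n, size=n_snp, replace=False)
        snp_distance[snp_idx] = rng.integers(0, 6, size=n_snp)
    # group consecutive island probes into islands of 1-6 members
    island_id = np.full(n, None, dtype=object)
    isl_positions = np.flatnonzero(rel == "island")
    i, isl_counter = 0, 0
    while i < len(isl_positions):
        size = int(rng.integers(1, 7))
        for j in isl_positions[i:i + size]:
            island_id[j] = f"CGI{isl_counter:06d}"
        isl_counter += 1
        i += size
    gene = np.where(
        feature == "intergenic", None,
        np.array([f"GENE{i:05d}" for i in rng.integers(0, max(n // 10, 1), size=n)],
                 dtype=object),
    )
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "strand": rng.choice(["+", "-"], size=n),
            "cgi_relation": rel,
            "island_id": island_id,
            "feature": feature,
            "gene": gene,
            "snp_distance": snp_distance,
            "blacklist_distance": np.full(n, np.nan),
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return ProbeAnnotation(df)


def generate_reference(config: SimulationConfig):
    """Build the 12-cell-type reference panel and its probe annotation.

    Differentiation-dynamic probes shift by ``delta_hem`` between HSC and
    a random non-empty subset of downstream cell types (always including
    at least one of the six mature types, so the hemDMP caller can see
    them); all other probes share one mean across cell types. Planted
    probes are drawn only from autosomal, variant-free probes so that
    probe filtering never removes truth.

    Returns ``(panel, annotation, truth_hem)``.
    """
    if config.n_probes < 100:
        raise ValidationError("n_probes must be >= 100")
    rng = np.random.default_rng(config.seed_sequence(0))
    ann = _make_annotation(config, rng)
    n = config.n_probes
    # baseline methylation tracks CpG density: islands are largely
    # unmethylated, open sea largely methylated (the genome-wide bimodal
    # pattern of somatic methylomes)
    rel = ann.df["cgi_relation"].to_numpy()
    base = np.empty(n)
    for relation, a, b in (
        ("island", 0.8, 6.0), ("shore", 1.5, 3.0),
        ("shelf", 3.0, 2.0), ("open_sea", 5.0, 1.5),
    ):
        mask = rel == relation
        base[mask] = rng.beta(a, b, size=int(mask.sum()))
    base = np.clip(base, 0.02, 0.98)

    clean = (
        ~ann.df["chrom"].astype(str).str.lower().isin({"chrx", "chry"})
        & ann.df["snp_distance"].isna()
    ).to_numpy()
    clean_idx = np.flatnonzero(clean)
    n_dyn = int(round(config.frac_hem_dynamic * n))
    if n_dyn > len(clean_idx):
        raise ValidationError("frac_hem_dynamic too large for clean probe pool")
    dyn_idx = np.sort(rng.choice(clean_idx, size=n_dyn, replace=False))

    profiles = np.tile(base, (12, 1))
    non_hsc = [ct for ct in CELL_TYPES if ct != "HSC"]
    for j in dyn_idx:
        # direction keeps the shifted value inside [0.02, 0.98]
        sign = 1.0 if base[j] <= 0.5 else -1.0
        k = int(rng.integers(1, len(non_hsc) + 1))
        chosen = rng.choice(non_hsc, size=k, replace=False).tolist()
        if not set(chosen) & set(MATURE_TYPES):
            chosen.append(rng.choice(MATURE_TYPES))
        for ct in chosen:
            ci = CELL_TYPES.index(ct)
            profiles[ci, j] = np.clip(base[j] + sign * config.delta_hem, 0.02, 0.98)

    panel = ReferencePanel(
        CELL_TYPES,
        pd.DataFrame(profiles, index=list(CELL_TYPES), columns=ann.probe_ids),
    )
    truth_hem = ProbeSet(
        "truth_hem",
        frozenset(ann.probe_ids[dyn_idx]),
        f"planted differentiation-dynamic probes, delta_hem={config.delta_hem}",
    )
    panel.annotation = ann
    panel.hem_truth = truth_hem
    return panel, ann, truth_hem


def _add_logit_noise(beta: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return beta
    z = logit(np.clip(beta, _EPS, 1 - _EPS))
    return expit(z + rng.normal(0.0, sd, size=beta.shape))


def generate_reference_samples(
    config: SimulationConfig, panel: ReferencePanel
) -> tuple[BetaMatrix, pd.Series]:
    """Noisy replicate methylomes of each pure reference cell type.

    These stand in for the sorted normal-cell-population arrays that a
    real study profiles; they feed the hemDMP caller and the
    hematopoiesis PCA. Returns (beta, labels: sample_id -> cell type).
    """
    rng = np.random.default_rng(config.seed_sequence(1))
    cols, labels, mats = [], [], []
    for ct in panel.cell_types:
        mu = panel.profiles.loc[ct].to_numpy()
        for r in range(config.n_replicates):
            mats.append(_add_logit_noise(mu, config.noise_sd, rng))
            cols.append(f"{ct}_rep{r:02d}")
            labels.append(ct)
    beta = BetaMatrix(
        pd.DataFrame(np.column_stack(mats), index=panel.probe_ids, columns=cols)
    )
    return beta, pd.Series(labels, index=pd.Index(cols, name="sample_id"))


def generate_cohort(config: SimulationConfig, panel: ReferencePanel):
    """Mix a three-subgroup leukemia cohort from the reference panel.

    Per sample: draw cell fractions from the Dirichlet, mix the reference
    profiles, add the planted subgroup shift on the truth-DMP probes
    (HM: +delta_hm, IM: +delta_im, LM: 0, signed per probe and clipped to
    [0,1]), then add logit-scale Gaussian noise. Genotype/karyotype/
    clinical labels are drawn with subgroup-dependent probabilities.

    Returns ``(beta, sheet, fractions, truth_dmp, labels)`` where
    *fractions* is the true sample x cell-type mixing matrix and *labels*
    the planted subgroup per sample.
    """
    if config.n_per_group < 2:
        raise ValidationError("n_per_group must be >= 2")
    if list(panel.probe_ids) != list(panel.profiles.columns):
        raise ValidationError("panel probes inconsistent")
    if panel.annotation is None or panel.hem_truth is None:
        raise ValidationError("panel lacks annotation/hem truth; use generate_reference")
    rng = np.random.default_rng(config.seed_sequence(2))
    ann = panel.annotation
    n = len(panel.probe_ids)

    clean = (
        ~ann.df["chrom"].astype(str).str.lower().isin({"chrx", "chry"})
        & ann.df["snp_distance"].isna()
    )
    nv_like = clean & ~ann.df.index.isin(panel.hem_truth.probe_ids)
    nv_ids = ann.df.index[nv_like]
    n_dmp = int(round(config.frac_subgroup_dmp * len(nv_ids)))
    is_island = ann.df.loc[nv_ids, "cgi_relation"] == "island"
    island_pool = nv_ids[is_island].to_numpy()
    other_pool = nv_ids[~is_island].to_numpy()
    n_isl = min(int(round(config.cgi_bias * n_dmp)), len(island_pool))
    n_oth = min(n_dmp - n_isl, len(other_pool))
    dmp_ids = np.concatenate([
        rng.choice(island_pool, size=n_isl, replace=False),
        rng.choice(other_pool, size=n_oth, replace=False),
    ])
    dmp_ids = np.sort(dmp_ids)
    sign = np.where(rng.random(len(dmp_ids)) < config.hyper_fraction, 1.0, -1.0)
    dmp_pos = ann.df.index.get_indexer(dmp_ids)

    groups = ("HM", "IM", "LM")
    deltas = {"HM": config.delta_hm, "IM": config.delta_im, "LM": 0.0}
    alpha = np.array([config.mixture_dirichlet[ct] for ct in panel.cell_types])
    profiles = panel.profiles.to_numpy()

    n_samples = 3 * config.n_per_group
    sample_ids = [f"JMML{i + 1:03d}" for i in range(n_samples)]
    labels = pd.Series(
        np.repeat(groups, config.n_per_group),
        index=pd.Index(sample_ids, name="sample_id"), name="methylation_group",
    )
    fractions = rng.dirichlet(alpha, size=n_samples)
    beta = fractions @ profiles  # samples x probes
    for i, g in enumerate(labels):
        if deltas[g] > 0:
            beta[i, dmp_pos] = np.clip(
                beta[i, dmp_pos] + sign * deltas[g], 0.0, 1.0
            )
    beta = _add_logit_noise(beta, config.noise_sd, rng)

    geno = np.concatenate([
        rng.choice(
            list(_GENOTYPE_PROBS[g]), size=config.n_per_group,
            p=list(_GENOTYPE_PROBS[g].values()),
        )
        for g in groups
    ])
    karyo = np.concatenate([
        rng.choice(
            list(_KARYOTYPE_PROBS[g]), size=config.n_per_group,
            p=list(_KARYOTYPE_PROBS[g].values()),
        )
        for g in groups
    ])
    age = np.concatenate([
        rng.lognormal(mean={"HM": 1.2, "IM": 0.5, "LM": -0.7}[g], sigma=0.6,
                      size=config.n_per_group)
        for g in groups
    ])
    plt_low = np.concatenate([
        rng.random(config.n_per_group) < _PLATELETS_LOW[g] for g in groups
    ])
    hbf = np.concatenate([
        rng.random(config.n_per_group) < _HBF_ELEVATED[g] for g in groups
    ])
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "cohort": "synthetic",
                "genotype": geno,
                "karyotype": karyo,
                "age_years": np.round(age, 2),
                "platelets_low": plt_low,
                "hbf_elevated": hbf,
                "hsct": True,
                "methylation_group": None,
            },
            index=labels.index,
        )
    )
    beta_mat = BetaMatrix(
        pd.DataFrame(beta.T, index=panel.probe_ids, columns=sample_ids)
    )
    frac_df = pd.DataFrame(
        fractions, index=labels.index, columns=list(panel.cell_types)
    )
    truth_dmp = ProbeSet(
        "truth_dmp",
        frozenset(dmp_ids),
        f"planted subgroup DMPs: delta_hm={config.delta_hm}, "
        f"delta_im={config.delta_im}, cgi_bias={config.cgi_bias}, "
        f"hyper_fraction={config.hyper_fraction}",
    )
    return beta_mat, sheet, frac_df, truth_dmp, labels


def generate_outcomes(labels: pd.Series, config: SimulationConfig) -> pd.DataFrame:
    """Competing-risk outcomes: relapse (1) vs TRM (2), 0 = censored.

    Latent exponential times per cause with group-specific hazards;
    observed time is the minimum of the two event times and an
    exponential censoring time; event is the cause achieving the
    minimum (0 when censoring wins).
    """
    hz = config.outcome_hazards
    missing = set(labels.unique()) - set(hz)
    if missing:
        raise ValidationError(f"no hazards for groups {sorted(missing)}")
    if config.censor_rate == 0 and all(
        h1 == 0 and h2 == 0 for h1, h2 in hz.values()
    ):
        raise ValidationError("all hazards and censor rate zero: no events possible")
    rng = np.random.default_rng(config.seed_sequence(3))
    n = len(labels)
    h1 = np.array([hz[g][0] for g in labels])
    h2 = np.array([hz[g][1] for g in labels])
    with np.errstate(divide="ignore"):
        t1 = rng.exponential(1.0, size=n) / np.where(h1 > 0, h1, np.nan)
        t2 = rng.exponential(1.0, size=n) / np.where(h2 > 0, h2, np.nan)
    t1 = np.where(np.isnan(t1), np.inf, t1)
    t2 = np.where(np.isnan(t2), np.inf, t2)
    if config.censor_rate > 0:
        tc = rng.exponential(1.0 / config.censor_rate, size=n)
    else:
        tc = np.full(n, np.inf)
    times = np.column_stack([tc, t1, t2])
    event = np.argmin(times, axis=1)
    time = times[np.arange(n), event]
    return pd.DataFrame(
        {
            "time": time,
            "event": event,
            "methylation_group": labels.to_numpy(),
        },
        index=labels.index,
    )
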