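"""Core data model: beta matrices, probe annotation, sample sheets, probe sets.

The methylation beta value — the fraction of methylated alleles at a CpG,
in [0, 1] — is the universal currency of the pipeline. All downstream
stages consume :class:`BetaMatrix` (probes x samples) together with a
:class:`ProbeAnnotation` giving each probe's genomic context (coordinates,
CpG-island relation, genomic feature, gene, and precomputed distances to
the nearest catalogued SNP / blacklisted variant).

Coordinates are 0-based half-open (BED convention). Missing betas are
permitted and propagated as NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CGI_RELATIONS = frozenset({"island", "shore", "shelf", "open_sea"})
FEATURES = frozenset(
    {"promoter", "utr5", "exon", "intron", "utr3", "intergenic", "ncRNA", "repeat"}
)
GENOTYPES = frozenset(
    {"PTPN11", "KRAS", "NRAS", "CBL", "NF1", "Noonan", "quintuple_negative"}
)
KARYOTYPES = frozenset({"normal", "monosomy7", "other"})
COHORTS = frozenset({"discovery", "validation", "synthetic"})
METHYLATION_GROUPS = frozenset({"HM", "IM", "LM"})

#: chromosome names treated as sex chromosomes (matched case-insensitively)
SEX_CHROMS = frozenset({"chrx", "chry", "x", "y"})

_BETA_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when an input violates the data model's invariants."""


@dataclass(frozen=True)
class ProbeSet:
    """A named set of CpG probes with a free-text provenance record.

    Used for hemDMPs (probes variable in normal hematopoietic
    differentiation), nvCpGs (their complement), subgroup-specific DMPs
    and classifier signatures.
    """

    name: str
    probe_ids: frozenset
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(self, "probe_ids", frozenset(self.probe_ids))

    def __len__(self) -> int:
        return len(self.probe_ids)

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.probe_ids

    def sorted_ids(self) -> list:
        return sorted(self.probe_ids)

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            for line in self.provenance.splitlines():
                fh.write(f"# {line}\n")
            fh.write(f"# name: {self.name}\n")
            for pid in self.sorted_ids():
                fh.write(pid + "\n")

    @classmethod
    def from_text(cls, path, name: str | None = None) -> "ProbeSet":
        ids, prov = [], []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    prov.append(line[1:].strip())
                elif line:
                    ids.append(line)
        set_name = name
        for p in prov:
            if p.startswith("name:") and set_name is None:
                set_name = p.split(":", 1)[1].strip()
        return cls(set_name or "probeset", frozenset(ids), "\n".join(prov))


class ProbeAnnotation:
    """Per-probe genomic context, indexed by ``probe_id``.

    Parameters
    ----------
    df
        DataFrame indexed by unique probe ids with columns ``chrom``,
        ``pos`` (0-based), ``strand``, ``cgi_relation``, ``island_id``,
        ``feature``, ``gene``, ``snp_distance``, ``blacklist_distance``.
        Distance columns may contain nulls (``no catalogued variant``).
    """

    REQUIRED = (
        "chrom",
        "pos",
        "strand",
        "cgi_relation",
        "island_id",
        "feature",
        "gene",
        "snp_distance",
        "blacklist_distance",
    )

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        if df.index.name != "probe_id":
            if "probe_id" in df.columns:
                df = df.set_index("probe_id")
            else:
                df.index.name = "probe_id"
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"annotation missing columns: {missing}")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()][:5].tolist()
            raise ValidationError(f"duplicate probe ids in annotation: {dups}")
        if (df["pos"] < 0).any():
            raise ValidationError("annotation contains negative positions")
        bad_rel = set(df["cgi_relation"].dropna()) - CGI_RELATIONS
        if bad_rel:
            raise ValidationError(f"unknown cgi_relation values: {sorted(bad_rel)}")
        bad_feat = set(df["feature"].dropna()) - FEATURES
        if bad_feat:
            raise ValidationError(f"unknown feature values: {sorted(bad_feat)}")
        island_no_id = (df["cgi_relation"] == "island") & df["island_id"].isna()
        if island_no_id.any():
            raise ValidationError(
                f"{int(island_no_id.sum())} island probes lack an island_id"
            )
        self.df = df

    @property
    def probe_ids(self) -> pd.Index:
        return self.df.index

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, probe_ids) -> "ProbeAnnotation":
        return ProbeAnnotation(self.df.loc[list(probe_ids)])

    def island_probes(self) -> ProbeSet:
        ids = self.df.index[self.df["cgi_relation"] == "island"]
        return ProbeSet("island_probes", frozenset(ids), "cgi_relation == island")

    def to_tsv(self, path) -> None:
        out = self.df.reset_index()
        out.insert(1, "start", out["pos"])
        out.insert(2, "end", out["pos"] + 1)
        cols = ["chrom", "start", "end", "probe_id"] + [
            c for c in out.columns if c not in {"chrom", "start", "end", "probe_id", "pos"}
        ]
        out[cols].to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path) -> "ProbeAnnotation":
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        df = df.rename(columns={"start": "pos"})
        return cls(df.drop(columns=["end"], errors="ignore").set_index("probe_id"))


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions in [0, 1]; NaN = missing."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        vals = self.df.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            out_of_range = (vals < -_BETA_TOL) | (vals > 1 + _BETA_TOL)
        if np.any(out_of_range & ~np.isnan(vals)):
            r, c = np.argwhere(out_of_range & ~np.isnan(vals))[0]
            raise ValidationError(
                f"beta value {vals[r, c]!r} outside [0,1] at probe "
                f"{self.df.index[r]!r}, sample {self.df.columns[c]!r}"
            )
        if self.df.index.duplicated().any():
            raise ValidationError("duplicate probe ids in beta matrix")
        if self.df.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in beta matrix")
        self.df.index.name = "probe_id"

    @property
    def probe_ids(self) -> pd.Index:
        return self.df.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.df.columns

    @property
    def shape(self):
        return self.df.shape

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    def select_probes(self, probe_ids) -> "BetaMatrix":
        ids = sorted(probe_ids) if isinstance(probe_ids, (set, frozenset)) else list(probe_ids)
        missing = set(ids) - set(self.df.index)
        if missing:
            raise KeyError(f"probes not in matrix: {sorted(missing)[:5]} ...")
        return BetaMatrix(self.df.loc[ids])

    def select_samples(self, sample_ids) -> "BetaMatrix":
        missing = set(sample_ids) - set(self.df.columns)
        if missing:
            raise KeyError(f"samples not in matrix: {sorted(missing)[:5]} ...")
        return BetaMatrix(self.df[list(sample_ids)])

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


def load_beta_matrix(path, annotation: ProbeAnnotation | None = None) -> BetaMatrix:
    """Read a beta matrix TSV (first column ``probe_id``, header = sample ids).

    Probes absent from *annotation* are reported via logging but kept;
    non-numeric cells and values outside [0, 1] raise errors naming the
    offending probe and sample.
    """
    try:
        parsed = pd.read_csv(
            path, sep="\t", index_col=0, na_values=["NA"],
            float_precision="round_trip",
        ).astype(float)
    except ValueError:
        # re-read as text to name the offending cell
        raw = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], dtype=str)
        for col in raw.columns:
            bad = raw[col][
                pd.to_numeric(raw[col], errors="coerce").isna() & raw[col].notna()
            ]
            if len(bad):
                raise ValidationError(
                    f"non-numeric value {bad.iloc[0]!r} at probe "
                    f"{bad.index[0]!r}, sample {col!r}"
                ) from None
        raise
    beta = BetaMatrix(parsed)
    if annotation is not None:
        unknown = beta.probe_ids.difference(annotation.probe_ids)
        if len(unknown):
            logger.warning(
                "%d probes in matrix absent from annotation (e.g. %s)",
                len(unknown), list(unknown[:3]),
            )
    return beta


class SampleSheet:
    """Per-sample clinical/technical metadata with closed vocabularies."""

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        if df.index.name != "sample_id":
            if "sample_id" in df.columns:
                df = df.set_index("sample_id")
            else:
                df.index.name = "sample_id"
        if df.index.duplicated().any():
            raise ValidationError("duplicate sample ids in sample sheet")
        for col, vocab in (
            ("cohort", COHORTS),
            ("genotype", GENOTYPES),
            ("karyotype", KARYOTYPES),
            ("methylation_group", METHYLATION_GROUPS),
        ):
            if col in df.columns:
                bad = set(df[col].dropna()) - vocab
                if bad:
                    raise ValidationError(f"invalid {col} values: {sorted(bad)}")
        if "age_years" in df.columns and (df["age_years"].dropna() < 0).any():
            raise ValidationError("negative age_years")
        self.df = df

    @property
    def sample_ids(self) -> pd.Index:
        return self.df.index

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "SampleSheet":
        return cls(pd.read_csv(path))


def filter_probes(
    beta: BetaMatrix,
    ann: ProbeAnnotation,
    snp_bp: int = 5,
    blacklist_bp: int = 3,
    drop_sex: bool = True,
) -> BetaMatrix:
    """Remove probes near catalogued variants and on sex chromosomes.

    A probe is dropped when ``snp_distance <= snp_bp``,
    ``blacklist_distance <= blacklist_bp``, or its chromosome is X/Y
    (if *drop_sex*). Null distances mean "no nearby variant" and never
    trigger removal. Negative thresholds disable the respective criterion,
    so ``snp_bp=blacklist_bp=-1, drop_sex=False`` is the identity.
    Returns a new matrix; the input is never mutated.
    """
    missing_ann = beta.probe_ids.difference(ann.probe_ids)
    if len(missing_ann):
        raise ValidationError(
            f"{len(missing_ann)} probes lack annotation (e.g. {list(missing_ann[:3])})"
        )
    sub = ann.df.loc[beta.probe_ids]
    snp = sub["snp_distance"].to_numpy(dtype=float)
    bl = sub["blacklist_distance"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        drop_snp = ~np.isnan(snp) & (snp <= snp_bp)
        drop_bl = ~np.isnan(bl) & (bl <= blacklist_bp)
    chrom_lower = sub["chrom"].astype(str).str.lower()
    drop_xy = chrom_lower.isin(SEX_CHROMS).to_numpy() if drop_sex else np.zeros(
        len(sub), dtype=bool
    )
    keep = ~(drop_snp | drop_bl | drop_xy)
    logger.info(
        "filter_probes: removed %d near-SNP, %d blacklisted, %d sex-chromosome; "
        "%d of %d retained",
        int(drop_snp.sum()), int(drop_bl.sum()), int(drop_xy.sum()),
        int(keep.sum()), len(keep),
    )
    if not keep.any():
        raise ValidationError("no probes retained after filtering")
    return BetaMatrix(beta.df.loc[keep])


def aggregate_islands(beta: BetaMatrix, ann: ProbeAnnotation) -> BetaMatrix:
    """Collapse island probes to one row per CpG island (mean beta per sample).

    Missing member values are ignored; an island whose members are all
    missing in a sample yields a missing output cell. Island rows are
    ordered lexicographically by island id.
    """
    sub = ann.df.loc[ann.df.index.intersection(beta.probe_ids)]
    island = sub[sub["cgi_relation"] == "island"]
    if island.empty:
        raise ValidationError("no island probes present")
    grouped = beta.df.loc[island.index].groupby(island["island_id"]).mean()
    grouped.index.name = "probe_id"
    return BetaMatrix(grouped.sort_index())
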