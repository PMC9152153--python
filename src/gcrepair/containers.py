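"""Core in-memory containers shared by every stage of the pipeline.

All tabular data rides on :class:`pandas.DataFrame`; the thin dataclasses here
add the validation the downstream statistics rely on (unique identifiers,
finite values, controlled vocabularies) and record bookkeeping flags such as
whether an expression matrix has been log-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class GcRepairError(ValueError):
    """Base error for invalid inputs anywhere in the package."""


VALID_STAGES = ("I", "II", "III", "IV", "NA")
SCORE_METHODS = ("student", "welch")
REGION_CLASSES = ("CGI", "open_sea", "other")


def _check_unique(values: Sequence, what: str) -> None:
    idx = pd.Index(values)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()[:5]
        raise GcRepairError(f"duplicate {what}: {dups}")


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric expression matrix.

    ``values`` is indexed by gene symbol with one column per sample.
    ``log_transformed`` records whether entries are on the log2 scale; the
    zero-fraction filter refuses log-scale input and ssGSEA expects it.
    """

    values: pd.DataFrame
    log_transformed: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            raise GcRepairError("ExpressionMatrix.values must be a DataFrame")
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        self.values = self.values.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)].copy(),
                                log_transformed=self.log_transformed)


@dataclass
class GeneSet:
    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise GcRepairError(f"gene set {self.name!r} is empty")
        _check_unique(self.genes, f"genes in set {self.name!r}")


@dataclass
class MarkerSet:
    """Named positive/negative marker gene lists (disjoint, both non-empty)."""

    name: str
    positive_genes: list[str]
    negative_genes: list[str]

    def __post_init__(self) -> None:
        if not self.positive_genes or not self.negative_genes:
            raise GcRepairError(
                f"marker set {self.name!r}: both gene lists must be non-empty "
                f"(got {len(self.positive_genes)} positive, "
                f"{len(self.negative_genes)} negative)")
        _check_unique(self.positive_genes, "positive genes")
        _check_unique(self.negative_genes, "negative genes")
        overlap = set(self.positive_genes) & set(self.negative_genes)
        if overlap:
            raise GcRepairError(
                f"marker set {self.name!r}: positive/negative lists overlap: "
                f"{sorted(overlap)[:5]}")


CLINICAL_COLUMNS = ["os_days", "os_event", "rfs_days", "rfs_event",
                    "stage", "age", "sex", "tissue"]


@dataclass
class ClinicalTable:
    """Per-sample survival/recurrence annotations, indexed by sample id.

    Required columns: ``os_days`` (non-negative), ``os_event`` (0/1),
    ``tissue`` ('tumor'|'normal').  Optional: ``rfs_days``/``rfs_event``
    (may be NaN), ``stage`` in {I,II,III,IV,NA}, ``age``, ``sex``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        _check_unique(df.index, "sample ids")
        for col in ("os_days", "os_event", "tissue"):
            if col not in df.columns:
                raise GcRepairError(f"clinical table missing column {col!r}")
        for col in ("rfs_days", "rfs_event", "stage", "age", "sex"):
            if col not in df.columns:
                df = df.copy()
                df[col] = np.nan
        for time_col in ("os_days", "rfs_days"):
            t = pd.to_numeric(df[time_col], errors="raise")
            if (t.dropna() < 0).any():
                raise GcRepairError(f"{time_col} contains negative times")
            df[time_col] = t
        for ev_col in ("os_event", "rfs_event"):
            e = pd.to_numeric(df[ev_col], errors="raise")
            bad = ~e.dropna().isin([0, 1])
            if bad.any():
                raise GcRepairError(f"{ev_col} flags must be 0/1")
            df[ev_col] = e
        stage = df["stage"].fillna("NA").astype(str)
        bad_stage = ~stage.isin(VALID_STAGES)
        if bad_stage.any():
            raise GcRepairError(
                f"unknown stage tokens: {sorted(stage[bad_stage].unique())}")
        df["stage"] = stage
        bad_tissue = ~df["tissue"].isin(["tumor", "normal"])
        if bad_tissue.any():
            raise GcRepairError(
                f"tissue must be tumor|normal, got "
                f"{sorted(df.loc[bad_tissue, 'tissue'].unique())}")
        self.df = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def tumors(self) -> "ClinicalTable":
        return ClinicalTable(self.df[self.df["tissue"] == "tumor"].copy())

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.df.loc[list(sample_ids)].copy())

    def endpoint(self, which: str) -> tuple[pd.Series, pd.Series]:
        """Return (time, event) series for endpoint 'os' or 'rfs',
        restricted to samples where both are observed."""
        if which not in ("os", "rfs"):
            raise GcRepairError(f"unknown endpoint {which!r} (use 'os'|'rfs')")
        t = self.df[f"{which}_days"]
        e = self.df[f"{which}_event"]
        keep = t.notna() & e.notna()
        return t[keep], e[keep].astype(int)


MAF_REQUIRED = ["Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification"]

# MAF variant-classification dialect.  Synonymous / non-coding classes are
# removed before TMB; everything protein-altering is kept.
SYNONYMOUS_CLASSES = frozenset({
    "Silent", "Intron", "3'UTR", "5'UTR", "3'Flank", "5'Flank", "IGR", "RNA",
})
NONSYNONYMOUS_CLASSES = frozenset({
    "Missense_Mutation", "Nonsense_Mutation", "Nonstop_Mutation",
    "Splice_Site", "Frame_Shift_Ins", "Frame_Shift_Del",
    "In_Frame_Ins", "In_Frame_Del", "Translation_Start_Site",
})
KNOWN_CLASSES = SYNONYMOUS_CLASSES | NONSYNONYMOUS_CLASSES


@dataclass
class MutationTable:
    """Somatic mutation records in a MAF-like layout.

    Columns: sample_id, gene, variant_classification, chrom, pos, ref, alt.
    Unknown variant classes are retained verbatim; ``unknown_classes`` lists
    them so callers can decide what to do.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("sample_id", "gene", "variant_classification"):
            if col not in self.df.columns:
                raise GcRepairError(f"mutation table missing column {col!r}")
        for col in ("chrom", "pos", "ref", "alt"):
            if col not in self.df.columns:
                self.df = self.df.copy()
                self.df[col] = np.nan
        pos = pd.to_numeric(self.df["pos"], errors="coerce")
        if (pos.dropna() < 1).any():
            raise GcRepairError("mutation positions must be >= 1 (1-based)")

    @property
    def unknown_classes(self) -> list[str]:
        vc = self.df["variant_classification"]
        return sorted(set(vc) - set(KNOWN_CLASSES))

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class MethylationData:
    """Probe x sample beta matrix plus per-probe genomic annotation.

    ``annotation`` is indexed by probe id with columns chrom, pos (1-based bp)
    and region_class in {CGI, open_sea, other}; an optional boolean
    ``promoter`` column marks promoter-associated CGI probes.
    """

    beta: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.beta.index, "probe ids")
        _check_unique(self.beta.columns, "sample ids")
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise GcRepairError("beta values must lie in [0, 1]")
        missing = set(self.beta.index) - set(self.annotation.index)
        if missing:
            raise GcRepairError(
                f"annotation missing for probes: {sorted(missing)[:5]}")
        for col in ("chrom", "pos", "region_class"):
            if col not in self.annotation.columns:
                raise GcRepairError(f"probe annotation missing column {col!r}")
        bad = ~self.annotation["region_class"].isin(REGION_CLASSES)
        if bad.any():
            raise GcRepairError(
                "region_class must be one of "
                f"{REGION_CLASSES}, got "
                f"{sorted(self.annotation.loc[bad, 'region_class'].unique())}")


@dataclass
class RiskModel:
    """A frozen scoring model: marker genes + method + calibrated cutoffs.

    ``survival_cutoff`` splits tumors into high/low risk (training-median
    convention); ``cancer_normal_cutoff`` separates tumor from normal tissue
    (ROC-derived).  Either cutoff may be None until calibrated, but must be
    finite once set.  The model is applied unchanged to new cohorts.
    """

    marker_set: MarkerSet
    score_method: str = "student"
    survival_cutoff: Optional[float] = None
    cancer_normal_cutoff: Optional[float] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.score_method not in SCORE_METHODS:
            raise GcRepairError(
                f"score_method must be one of {SCORE_METHODS}, "
                f"got {self.score_method!r}")
        for name in ("survival_cutoff", "cancer_normal_cutoff"):
            val = getattr(self, name)
            if val is not None:
                if not np.isfinite(val):
                    raise GcRepairError(f"{name} must be finite, got {val}")
                setattr(self, name, float(val))
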