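"""Tumor mutational burden and substitution-class summaries."""

from __future__ import annotations

import logging
from typing import Sequence

import pandas as pd

from .containers import (GcRepairError, MutationTable,
                         NONSYNONYMOUS_CLASSES, SYNONYMOUS_CLASSES)

log = logging.getLogger(__name__)

DEFAULT_INTERROGATED_MB = 38.0  # whole-exome convention

SNV_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def filter_nonsynonymous(muts: MutationTable) -> MutationTable:
    """Drop synonymous / non-coding variant classes before TMB.

    Removes {Silent, Intron, 3'UTR, 5'UTR, 3'Flank, 5'Flank, IGR, RNA};
    keeps protein-altering classes.  Unknown classes are kept conservatively
    with a warning.
    """
    vc = muts.df["variant_classification"]
    unknown = sorted(set(vc) - SYNONYMOUS_CLASSES - NONSYNONYMOUS_CLASSES)
    if unknown:
        log.warning("unknown variant classes kept conservatively: %s",
                    unknown)
    keep = ~vc.isin(SYNONYMOUS_CLASSES)
    return MutationTable(muts.df[keep].copy())


def compute_tmb(muts: MutationTable,
                interrogated_mb: float = DEFAULT_INTERROGATED_MB,
                sample_roster: Sequence[str] | None = None) -> pd.Series:
    """Mutations per megabase per sample.

    ``muts`` should already be nonsynonymous-filtered.  Samples listed in
    ``sample_roster`` but absent from the table get TMB 0.
    """
    if interrogated_mb <= 0:
        raise GcRepairError(
            f"interrogated_mb must be > 0, got {interrogated_mb}")
    counts = muts.df.groupby("sample_id").size()
    if sample_roster is not None:
        counts = counts.reindex(list(sample_roster), fill_value=0)
    return (counts / interrogated_mb).rename("tmb").astype(float)


def snv_class_summary(muts: MutationTable) -> pd.Series:
    """Counts of the six substitution classes (pyrimidine-reference
    convention: purine-reference SNVs are complemented, e.g. G>A counts as
    C>T).  Indels and malformed records are skipped."""
    counts = dict.fromkeys(SNV_CLASSES, 0)
    skipped = 0
    for ref, alt in zip(muts.df["ref"], muts.df["alt"]):
        if not (isinstance(ref, str) and isinstance(alt, str)):
            continue
        ref, alt = ref.upper(), alt.upper()
        if len(ref) != 1 or len(alt) != 1:
            continue  # indel or MNV: not an SNV
        if ref not in _COMPLEMENT or alt not in _COMPLEMENT or ref == alt:
            skipped += 1
            continue
        if ref in ("A", "G"):
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        counts[f"{ref}>{alt}"] += 1
    if skipped:
        log.warning("snv_class_summary: skipped %d malformed SNV records",
                    skipped)
    return pd.Series(counts, name="count").reindex(list(SNV_CLASSES))
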