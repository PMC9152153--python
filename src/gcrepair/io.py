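"""Readers and writers for the plain-text formats the pipeline consumes.

TSV for expression / clinical / methylation tables, GMT for gene sets, a
MAF-dialect TSV for somatic mutations, and JSON for serialized risk models.
Provenance comment lines starting with ``#`` are ignored on read.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .containers import (
    ClinicalTable,
    ExpressionMatrix,
    GcRepairError,
    GeneSet,
    MarkerSet,
    MethylationData,
    MutationTable,
    RiskModel,
    MAF_REQUIRED,
)

log = logging.getLogger(__name__)

NA_TOKENS = ("NA", "NaN", "nan", "")

PathLike = Union[str, Path]

MODEL_FORMAT_VERSION = 1


def _read_tsv(path: PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise GcRepairError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise GcRepairError(f"empty file: {path}")
    return pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                       comment="#", keep_default_na=False)


def _to_numeric(df: pd.DataFrame, path: PathLike) -> pd.DataFrame:
    """Convert a string frame to float, mapping NA tokens to NaN and naming
    the offending cell on any other non-numeric value."""
    df = df.replace(list(NA_TOKENS), np.nan)
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise GcRepairError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at row "
            f"{df.index[r]!r}, column {df.columns[c]!r}")
    return out


def read_expression(path: PathLike, orientation: str = "genes_by_rows",
                    log_transformed: bool = False) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column = gene symbols).

    ``orientation='samples_by_rows'`` transposes on read.  Duplicate gene
    symbols (e.g. multiple array probes) are collapsed by their mean, and the
    collapse is logged.  NA tokens {NA, NaN, ""} become missing values to be
    imputed downstream.
    """
    if orientation not in ("genes_by_rows", "samples_by_rows"):
        raise GcRepairError(f"unknown orientation {orientation!r}")
    raw = _read_tsv(path)
    values = _to_numeric(raw, path)
    if orientation == "samples_by_rows":
        values = values.T
    if values.index.has_duplicates:
        n_dup = int(values.index.duplicated().sum())
        log.info("collapsing %d duplicate gene symbols by mean in %s",
                 n_dup, path)
        values = values.groupby(level=0, sort=False).mean()
    values.index.name = None
    values.columns.name = None
    return ExpressionMatrix(values, log_transformed=log_transformed)


def write_expression(expr: ExpressionMatrix, path: PathLike,
                     header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        expr.values.to_csv(fh, sep="\t", index_label="gene")


def read_gmt(path: PathLike) -> list[GeneSet]:
    """Parse a GMT file: ``name TAB description TAB gene1 TAB gene2 ...``."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GcRepairError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene ({len(fields)} fields found)")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise GcRepairError(f"{path}:{lineno}: gene set {name!r} "
                                    "has an empty gene list")
            sets.append(GeneSet(name=name, genes=genes))
    if not sets:
        raise GcRepairError(f"{path}: no gene sets found")
    return sets


def write_gmt(gene_sets: list[GeneSet], path: PathLike) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, "na", *gs.genes]) + "\n")


def read_clinical(path: PathLike) -> ClinicalTable:
    raw = _read_tsv(path)
    df = raw.replace(list(NA_TOKENS), np.nan)
    for col in ("os_days", "os_event", "rfs_days", "rfs_event", "age"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    return ClinicalTable(df)


def write_clinical(clin: ClinicalTable, path: PathLike) -> None:
    clin.df.to_csv(path, sep="\t", index_label="sample_id")


_MAF_RENAME = {
    "Tumor_Sample_Barcode": "sample_id",
    "Hugo_Symbol": "gene",
    "Variant_Classification": "variant_classification",
    "Chromosome": "chrom",
    "Start_Position": "pos",
    "Reference_Allele": "ref",
    "Tumor_Seq_Allele2": "alt",
}


def read_maf(path: PathLike) -> MutationTable:
    """Read a MAF-dialect TSV.  Requires Tumor_Sample_Barcode, Hugo_Symbol
    and Variant_Classification; unknown classifications are kept verbatim
    and logged (filtering is a separate, explicit step)."""
    path = Path(path)
    if not path.exists():
        raise GcRepairError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    missing = [c for c in MAF_REQUIRED if c not in df.columns]
    if missing:
        raise GcRepairError(f"{path}: missing required MAF column(s) "
                            f"{missing}")
    df = df.rename(columns=_MAF_RENAME)
    keep = [c for c in _MAF_RENAME.values() if c in df.columns]
    df = df[keep].replace(list(NA_TOKENS), np.nan)
    if "pos" in df.columns:
        df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    table = MutationTable(df)
    if table.unknown_classes:
        log.warning("%s: unknown variant classifications kept verbatim: %s",
                    path, table.unknown_classes)
    return table


def write_maf(muts: MutationTable, path: PathLike) -> None:
    inverse = {v: k for k, v in _MAF_RENAME.items()}
    muts.df.rename(columns=inverse).to_csv(path, sep="\t", index=False)


def read_methylation(beta_path: PathLike,
                     annotation_path: PathLike) -> MethylationData:
    beta = _to_numeric(_read_tsv(beta_path), beta_path)
    ann = _read_tsv(annotation_path)
    ann["pos"] = pd.to_numeric(ann["pos"], errors="raise").astype(int)
    if "promoter" in ann.columns:
        ann["promoter"] = ann["promoter"].isin(["1", "True", "true", "yes"])
    return MethylationData(beta=beta, annotation=ann)


def write_methylation(meth: MethylationData, beta_path: PathLike,
                      annotation_path: PathLike) -> None:
    meth.beta.to_csv(beta_path, sep="\t", index_label="probe_id")
    ann = meth.annotation.copy()
    if "promoter" in ann.columns:
        ann["promoter"] = ann["promoter"].astype(int)
    ann.to_csv(annotation_path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# Risk-model persistence (human-readable JSON, round-trip exact)
# ---------------------------------------------------------------------------

def save_model(model: RiskModel, path: PathLike) -> None:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "marker_set": {
            "name": model.marker_set.name,
            "positive_genes": model.marker_set.positive_genes,
            "negative_genes": model.marker_set.negative_genes,
        },
        "score_method": model.score_method,
        "survival_cutoff": model.survival_cutoff,
        "cancer_normal_cutoff": model.cancer_normal_cutoff,
        "provenance": model.provenance,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def _model_from_payload(payload: dict, source: str) -> RiskModel:
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise GcRepairError(
            f"{source}: model format version {version!r} not supported "
            f"(expected {MODEL_FORMAT_VERSION})")
    try:
        ms = payload["marker_set"]
        marker_set = MarkerSet(name=ms["name"],
                               positive_genes=list(ms["positive_genes"]),
                               negative_genes=list(ms["negative_genes"]))
        return RiskModel(
            marker_set=marker_set,
            score_method=payload["score_method"],
            survival_cutoff=payload["survival_cutoff"],
            cancer_normal_cutoff=payload["cancer_normal_cutoff"],
            provenance=dict(payload.get("provenance", {})),
        )
    except (KeyError, TypeError) as exc:
        raise GcRepairError(f"{source}: corrupted model file: {exc}") from exc


def load_model(path: PathLike) -> RiskModel:
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise GcRepairError(f"{path}: corrupted model file: {exc}") from exc
    return _model_from_payload(payload, str(path))


# ---------------------------------------------------------------------------
# Packaged fixtures: the published 76-gene marker set and model cutoffs
# ---------------------------------------------------------------------------

def load_gc76() -> MarkerSet:
    """The published 37 positive + 39 negative marker genes
    ("GC-SSA-NHEJ-76")."""
    ref = resources.files("gcrepair.data") / "gc_ssa_nhej_76.gmt"
    with resources.as_file(ref) as path:
        pos, neg = read_gmt(path)
    return MarkerSet(name="GC-SSA-NHEJ-76",
                     positive_genes=pos.genes, negative_genes=neg.genes)


def load_published_model() -> RiskModel:
    """The published model: 76 markers, Student t scoring, survival cutoff
    3.46 and tumor/normal cutoff 0.008."""
    ref = resources.files("gcrepair.data") / "gc_ssa_nhej_model.json"
    payload = json.loads(ref.read_text())
    return _model_from_payload(payload, "packaged model")
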