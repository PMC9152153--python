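"""Expression and clinical filters applied before any scoring.

The order used throughout the analysis is: drop genes that are zero in more
than 70% of samples, mask the remaining zeros as missing, impute them with
gene-space K-nearest-neighbours, log2-transform, and drop patients who died
within 10 days of sampling.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import nan_euclidean_distances

from .containers import ClinicalTable, ExpressionMatrix, GcRepairError

log = logging.getLogger(__name__)


def filter_low_expressed(expr: ExpressionMatrix,
                         max_zero_frac: float = 0.7) -> ExpressionMatrix:
    """Remove genes whose raw expression is zero (or missing) in *more than*
    ``max_zero_frac`` of samples.

    The inequality is strict: a gene at exactly the threshold is retained.
    Defined on the raw scale only — zeros are not meaningful after log2.
    """
    if expr.log_transformed:
        raise GcRepairError("zero-fraction filter requires raw-scale "
                            "expression (input is log-transformed)")
    if not 0 <= max_zero_frac <= 1:
        raise GcRepairError(f"max_zero_frac must be in [0,1], "
                            f"got {max_zero_frac}")
    vals = expr.values
    zero_frac = ((vals == 0) | vals.isna()).mean(axis=1)
    keep = zero_frac <= max_zero_frac
    log.info("zero-fraction filter: kept %d/%d genes at threshold %.2f",
             int(keep.sum()), len(keep), max_zero_frac)
    return ExpressionMatrix(vals.loc[keep].copy(), log_transformed=False)


def mask_zeros(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Mark remaining raw zeros as missing so they get imputed."""
    if expr.log_transformed:
        raise GcRepairError("mask_zeros operates on raw-scale expression")
    vals = expr.values.mask(expr.values == 0)
    return ExpressionMatrix(vals, log_transformed=False)


def knn_impute(expr: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Impute each missing entry with the mean of the k nearest genes.

    Distances between genes are Euclidean over shared non-missing samples,
    rescaled by the fraction observed (the standard NaN-Euclidean metric).
    Only genes with an observed value at the missing sample are candidate
    neighbours; distance ties break on the lower gene index.
    """
    if k < 1:
        raise GcRepairError(f"k must be >= 1, got {k}")
    vals = expr.values
    n_genes = len(vals)
    if k >= n_genes:
        raise GcRepairError(
            f"k={k} is not smaller than the gene count ({n_genes})")
    mask = vals.isna().to_numpy()
    if not mask.any():
        return ExpressionMatrix(vals.copy(),
                                log_transformed=expr.log_transformed)
    all_missing = mask.all(axis=1)
    if all_missing.any():
        genes = vals.index[all_missing].tolist()
        raise GcRepairError(f"gene(s) with all values missing: {genes[:10]}")

    X = vals.to_numpy(dtype=float)
    dist = nan_euclidean_distances(X)  # symmetric, NaN-aware
    np.fill_diagonal(dist, np.inf)
    out = X.copy()
    for g, s in zip(*np.where(mask)):
        candidates = np.where(~mask[:, s])[0]
        d = dist[g, candidates]
        finite = np.isfinite(d)
        candidates, d = candidates[finite], d[finite]
        if len(candidates) == 0:
            raise GcRepairError(
                f"no donor gene for {vals.index[g]!r} at sample "
                f"{vals.columns[s]!r}")
        order = np.argsort(d, kind="stable")  # ties -> lower gene index
        nearest = candidates[order[:k]]
        out[g, s] = X[nearest, s].mean()
    imputed = pd.DataFrame(out, index=vals.index, columns=vals.columns)
    return ExpressionMatrix(imputed, log_transformed=expr.log_transformed)


def log2_transform(expr: ExpressionMatrix,
                   pseudocount: float = 1.0) -> ExpressionMatrix:
    if expr.log_transformed:
        raise GcRepairError("expression is already log-transformed")
    vals = expr.values
    if (vals < 0).any().any():
        raise GcRepairError("negative expression values cannot be "
                            "log2-transformed")
    return ExpressionMatrix(np.log2(vals + pseudocount),
                            log_transformed=True)


def filter_clinical(clin: ClinicalTable,
                    min_days: float = 10.0) -> ClinicalTable:
    """Drop patients who *died* within ``min_days`` of follow-up start.

    Early-censored samples are retained — the exclusion targets deaths only.
    """
    df = clin.df
    early_death = (df["os_event"] == 1) & (df["os_days"] <= min_days)
    log.info("clinical filter: removed %d early deaths (<= %g days)",
             int(early_death.sum()), min_days)
    return ClinicalTable(df[~early_death].copy())


def label_outcome(clin: ClinicalTable,
                  horizon_days: float = 365.0) -> pd.Series:
    """One-year outcome labels: 'good' for survival past the horizon,
    'poor' for death within it, 'undetermined' for censoring before it."""
    df = clin.df
    labels = pd.Series("undetermined", index=df.index, name="outcome")
    labels[df["os_days"] > horizon_days] = "good"
    labels[(df["os_event"] == 1) & (df["os_days"] <= horizon_days)] = "poor"
    return labels
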