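"""Marker-gene selection: genes whose expression tracks DNA-repair activity.

The target is the (z-scored, averaged) ssGSEA score of the chosen repair
gene sets; genes with |Pearson r| above a threshold and a Benjamini-Hochberg
q below the FDR cut become the positive/negative marker lists.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, GcRepairError, MarkerSet

log = logging.getLogger(__name__)

R_THRESHOLD = 0.4
FDR_THRESHOLD = 0.001


def combine_target(score_rows: pd.DataFrame) -> pd.Series:
    """Combine gene-set score rows into one per-sample target vector.

    Each row is z-scored across samples (population sd) and the rows are
    averaged; a single row simply comes back z-scored.  Zero-variance rows
    are dropped with a warning; if nothing is left, that is an error.
    """
    if len(score_rows) == 0:
        raise GcRepairError("combine_target needs at least one score row")
    sd = score_rows.std(axis=1, ddof=0)
    flat = sd == 0
    if flat.any():
        log.warning("combine_target: dropping zero-variance rows %s",
                    list(score_rows.index[flat]))
    kept = score_rows[~flat]
    if len(kept) == 0:
        raise GcRepairError("all score rows have zero variance")
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd[~flat], axis=0)
    return z.mean(axis=0).rename("target")


def correlate_genes(expr: ExpressionMatrix,
                    target: pd.Series) -> pd.DataFrame:
    """Pearson correlation of every gene with the target vector.

    Returns a frame indexed by gene with columns ``r``, ``p`` (two-sided,
    t-distribution) and ``q`` (BH across all testable genes).  Constant
    genes get NaN throughout and never enter selection.
    """
    common = expr.values.columns.intersection(target.index)
    if len(common) < 3:
        raise GcRepairError("correlation needs at least 3 shared samples")
    X = expr.values.loc[:, common].to_numpy(dtype=float)
    y = target.loc[common].to_numpy(dtype=float)
    n = len(common)
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((Xc ** 2).sum(axis=1))
    sy = np.sqrt((yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / (sx * sy)
    r = np.where(sx == 0, np.nan, r)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r ** 2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    p = np.where(np.isnan(r), np.nan, p)
    out = pd.DataFrame({"r": r, "p": p}, index=expr.values.index)
    testable = out["p"].notna()
    q = np.full(len(out), np.nan)
    if testable.any():
        q[testable.to_numpy()] = bh_adjust(out.loc[testable, "p"].to_numpy())
    out["q"] = q
    return out


def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise GcRepairError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_markers(corr: pd.DataFrame, r_threshold: float = R_THRESHOLD,
                   fdr: float = FDR_THRESHOLD,
                   name: str = "selected") -> MarkerSet:
    """Threshold the correlation table into a marker set.

    Strict inequalities on both criteria: positive genes satisfy
    r > r_threshold, negative genes r < -r_threshold, both with q < fdr.
    Output gene lists are symbol-sorted for determinism.
    """
    if not (0 < r_threshold < 1):
        raise GcRepairError("r_threshold must be in (0, 1)")
    if not (0 < fdr < 1):
        raise GcRepairError("fdr must be in (0, 1)")
    ok = corr["r"].notna() & (corr["q"] < fdr)
    pos = sorted(corr.index[ok & (corr["r"] > r_threshold)])
    neg = sorted(corr.index[ok & (corr["r"] < -r_threshold)])
    if not pos or not neg:
        raise GcRepairError(
            f"marker selection produced {len(pos)} positive and {len(neg)} "
            "negative genes; relax r_threshold/fdr or check the target")
    return MarkerSet(name=name, positive_genes=pos, negative_genes=neg)
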