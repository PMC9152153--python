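"""The SSA-NHEJ score and the two classifiers built on it.

The per-sample score is the two-sample t statistic comparing the sample's
expression over the positive marker genes against the negative marker
genes; a high score means the proliferative/repair program dominates.  The
survival classifier (HR-LR) splits tumors at the training-median score; the
tumor/normal classifier uses a ROC-derived cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (ExpressionMatrix, GcRepairError, MarkerSet,
                         RiskModel)

log = logging.getLogger(__name__)

TUMOR, NORMAL = "tumor", "normal"
HIGH_RISK, LOW_RISK = "high_risk", "low_risk"


def _present_genes(expr: ExpressionMatrix, genes: list[str],
                   which: str) -> list[str]:
    present = [g for g in genes if g in expr.values.index]
    if len(present) < 2:
        raise GcRepairError(
            f"{which} marker list: need >= 2 genes present in the "
            f"expression matrix, found {len(present)} of {len(genes)}")
    if len(present) < 0.5 * len(genes):
        log.warning("%s marker list: only %d/%d genes present (<50%%); "
                    "scores may be unstable", which, len(present),
                    len(genes))
    return present


def ssa_nhej_score(expr: ExpressionMatrix, markers: MarkerSet,
                   method: str = "student") -> pd.Series:
    """Per-sample SSA-NHEJ score (two-sample t statistic, positive vs
    negative marker genes).

    ``method='student'`` pools variances (default); ``'welch'`` does not.
    Marker lists are intersected with the matrix genes (case-sensitive
    symbols); fewer than 2 present genes in either list is an error, below
    50% coverage a logged warning.
    """
    if method not in ("student", "welch"):
        raise GcRepairError(f"unknown score method {method!r}")
    if not expr.log_transformed:
        log.warning("scoring non-log-transformed expression")
    pos = _present_genes(expr, markers.positive_genes, "positive")
    neg = _present_genes(expr, markers.negative_genes, "negative")
    a = expr.values.loc[pos].to_numpy(dtype=float)
    b = expr.values.loc[neg].to_numpy(dtype=float)
    t = stats.ttest_ind(a, b, axis=0, equal_var=(method == "student"))
    return pd.Series(t.statistic, index=expr.sample_ids, name="ssa_nhej_score")


def fit_hr_lr(training_expr: ExpressionMatrix, markers: MarkerSet,
              method: str = "student",
              provenance: dict | None = None) -> RiskModel:
    """Calibrate the survival cutoff as the median training score.

    The training cohort must be tumor samples; even-length cohorts use the
    mean-of-middle-two median convention.
    """
    n = len(training_expr.sample_ids)
    if n < 10:
        raise GcRepairError(f"need >= 10 training samples, got {n}")
    scores = ssa_nhej_score(training_expr, markers, method=method)
    cutoff = float(np.median(scores.to_numpy()))
    prov = {"training_n": n, **(provenance or {})}
    return RiskModel(marker_set=markers, score_method=method,
                     survival_cutoff=cutoff, provenance=prov)


def classify_risk(scores: pd.Series, model: RiskModel) -> pd.Series:
    """High/low risk labels: score > cutoff -> low_risk (better outcome),
    score <= cutoff -> high_risk.  The boundary goes to high_risk."""
    if model.survival_cutoff is None:
        raise GcRepairError("model has no survival cutoff; fit it first")
    labels = np.where(scores > model.survival_cutoff, LOW_RISK, HIGH_RISK)
    return pd.Series(labels, index=scores.index, name="risk_class")


@dataclass
class RocCurve:
    """ROC curve over all distinct score thresholds (rule: score >= cutoff
    -> tumor).  Cutoffs are descending; sensitivity is non-decreasing along
    the array (i.e. non-increasing in the cutoff value)."""

    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    scores: pd.Series = field(repr=False, default=None)
    truth: pd.Series = field(repr=False, default=None)


def roc_curve(scores: pd.Series, truth: pd.Series) -> RocCurve:
    """ROC of the score against tumor/normal truth labels.

    Thresholds are the distinct score values (ties collapse onto one
    threshold) plus a sentinel above the maximum; AUC is the trapezoidal
    area over (1-specificity, sensitivity).
    """
    common = scores.index.intersection(truth.index)
    s = scores.loc[common].to_numpy(dtype=float)
    y = truth.loc[common]
    bad = set(y.unique()) - {TUMOR, NORMAL}
    if bad:
        raise GcRepairError(f"truth labels must be tumor|normal, got {bad}")
    is_t = (y == TUMOR).to_numpy()
    n_t, n_n = int(is_t.sum()), int((~is_t).sum())
    if n_t == 0 or n_n == 0:
        raise GcRepairError("both classes must be present for a ROC curve")
    uniq = np.unique(s)  # ascending
    cutoffs = np.concatenate([[np.inf], uniq[::-1]])
    sens = np.empty(len(cutoffs))
    spec = np.empty(len(cutoffs))
    for i, c in enumerate(cutoffs):
        called = s >= c
        sens[i] = (called & is_t).sum() / n_t
        spec[i] = (~called & ~is_t).sum() / n_n
    fpr = 1 - spec
    auc = float(np.trapezoid(sens, fpr))
    return RocCurve(cutoffs=cutoffs, sensitivity=sens, specificity=spec,
                    auc=auc,
                    scores=pd.Series(s, index=common),
                    truth=pd.Series(y.to_numpy(), index=common))


def select_cutoff(roc: RocCurve) -> float:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Ties break toward the smaller cutoff.  When the classes are perfectly
    separated the returned cutoff is the midpoint of the separating gap
    (any value in the gap achieves J = 1; the midpoint is the documented
    convention).
    """
    j = roc.sensitivity + roc.specificity - 1
    best = j.max()
    if np.isclose(best, 1.0) and roc.scores is not None:
        s, y = roc.scores, roc.truth
        lo = s[y == TUMOR].min()
        hi = s[y == NORMAL].max()
        if hi < lo:
            return float((lo + hi) / 2)
    winners = roc.cutoffs[np.isclose(j, best)]
    return float(winners.min())


def classify_cancer_normal(scores: pd.Series,
                           cutoff: float) -> pd.Series:
    """Tumor/normal call: score >= cutoff -> tumor (boundary inclusive for
    tumor, unlike the survival split)."""
    if not np.isfinite(cutoff):
        raise GcRepairError("cutoff must be finite")
    labels = np.where(scores >= cutoff, TUMOR, NORMAL)
    return pd.Series(labels, index=scores.index, name="status")


@dataclass
class ClassificationMetrics:
    tpr: float          # sensitivity
    specificity: float  # 1 - FPR
    accuracy: float
    precision: float
    f_measure: float


def classification_metrics(pred: pd.Series, truth: pd.Series,
                           positive: str = TUMOR) -> ClassificationMetrics:
    """Confusion-matrix metrics; ratios with a zero denominator are NaN."""
    common = pred.index.intersection(truth.index)
    p, t = pred.loc[common], truth.loc[common]
    vocab = set(p.unique()) | set(t.unique())
    if not vocab <= {TUMOR, NORMAL}:
        raise GcRepairError(
            f"labels must be tumor|normal, got {sorted(vocab)}")
    tp = int(((p == positive) & (t == positive)).sum())
    fp = int(((p == positive) & (t != positive)).sum())
    fn = int(((p != positive) & (t == positive)).sum())
    tn = int(((p != positive) & (t != positive)).sum())

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else float("nan")

    tpr = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    acc = ratio(tp + tn, tp + tn + fp + fn)
    prec = ratio(tp, tp + fp)
    f = ratio(2 * prec * tpr, prec + tpr) if (prec + tpr) > 0 else float("nan")
    return ClassificationMetrics(tpr=tpr, specificity=spec, accuracy=acc,
                                 precision=prec, f_measure=f)
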