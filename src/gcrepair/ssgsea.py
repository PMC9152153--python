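"""Single-sample gene-set enrichment (ssGSEA) scoring.

The score for one sample and one gene set is the classic weighted
ECDF-difference sum: genes are ranked by expression, the in-set empirical
distribution is weighted by rank^alpha (normalised to one), the out-of-set
distribution is uniform, and the enrichment score is the sum of the
difference of the two running distributions over all rank positions.  The
score is rank-based and therefore invariant to any strictly monotone
transform of the expression column.

Conventions (fixed for determinism):
  * ranks are ascending with average ties (the top gene has rank N);
  * the descent order through the ranked list breaks rank ties by gene
    position in the input;
  * a set covering the whole gene universe has an empty complement and its
    score is defined as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import ExpressionMatrix, GcRepairError, GeneSet

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.25


@dataclass
class GeneSetScoreMatrix:
    """Set x sample matrix of enrichment scores."""

    scores: pd.DataFrame          # set names x sample ids
    alpha: float
    normalized: bool

    @property
    def set_names(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)


def rank_ties(expr_column: pd.Series | np.ndarray) -> np.ndarray:
    """Descending ranks with average ties: the largest value gets rank 1."""
    x = np.asarray(expr_column, dtype=float)
    return rankdata(-x, method="average")


def _es_from_order(in_mask_ordered: np.ndarray, weights_ordered: np.ndarray,
                   n_out: int) -> float:
    w = np.where(in_mask_ordered, weights_ordered, 0.0)
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~in_mask_ordered) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea_sample(expr_column: pd.Series, gene_set: GeneSet,
                  alpha: float = DEFAULT_ALPHA) -> float:
    """Enrichment score of one gene set in one sample.

    ``expr_column`` is the sample's expression over the full gene universe,
    indexed by gene symbol.  Set genes absent from the universe are ignored;
    if none is present an error names the set.
    """
    genes = expr_column.index
    member = genes.isin(gene_set.genes)
    m = int(member.sum())
    if m == 0:
        raise GcRepairError(
            f"no gene of set {gene_set.name!r} present in the expression "
            "matrix")
    n = len(genes)
    if m == n:  # empty complement: defined as 0
        return 0.0
    x = expr_column.to_numpy(dtype=float)
    ranks = rankdata(x, method="average")          # top gene has rank n
    order = np.lexsort((np.arange(n), -ranks))     # descending, stable ties
    weights = ranks[order] ** alpha
    return _es_from_order(member[order], weights, n - m)


def ssgsea_matrix(expr: ExpressionMatrix, gene_sets: list[GeneSet],
                  alpha: float = DEFAULT_ALPHA,
                  normalize: bool = False) -> GeneSetScoreMatrix:
    """Score every gene set in every sample.

    With ``normalize=True`` the whole matrix is divided by its global score
    range (max - min), the usual cross-sample normalisation of ssGSEA
    output.  Expects log-scale expression (a warning is logged otherwise —
    the ranks, and hence the scores, are unaffected by monotone rescaling
    within a sample, but the convention is recorded).
    """
    if not expr.log_transformed:
        log.warning("ssgsea_matrix called on non-log-transformed expression")
    genes = expr.values.index
    n = len(genes)
    membership = np.vstack([genes.isin(gs.genes) for gs in gene_sets])
    m = membership.sum(axis=1)
    for gs, mi in zip(gene_sets, m):
        if mi == 0:
            raise GcRepairError(
                f"no gene of set {gs.name!r} present in the expression "
                "matrix")
    full = m == n
    X = expr.values.to_numpy(dtype=float)
    out = np.zeros((len(gene_sets), X.shape[1]))
    idx = np.arange(n)
    for j in range(X.shape[1]):
        ranks = rankdata(X[:, j], method="average")
        order = np.lexsort((idx, -ranks))
        w_ord = ranks[order] ** alpha
        memb_ord = membership[:, order]
        w = np.where(memb_ord, w_ord[None, :], 0.0)
        p_in = np.cumsum(w, axis=1) / w.sum(axis=1, keepdims=True)
        p_out = np.cumsum(~memb_ord, axis=1) / np.maximum(n - m, 1)[:, None]
        out[:, j] = np.sum(p_in - p_out, axis=1)
    out[full, :] = 0.0
    scores = pd.DataFrame(out, index=[gs.name for gs in gene_sets],
                          columns=expr.sample_ids)
    if normalize:
        rng = scores.to_numpy().max() - scores.to_numpy().min()
        if rng > 0:
            scores = scores / rng
    return GeneSetScoreMatrix(scores=scores, alpha=alpha,
                              normalized=normalize)
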