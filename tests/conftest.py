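"""Shared fixtures: one default synthetic cohort (seed 17) processed once
per session, plus small hand-made tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gcrepair import preprocess as prep
from gcrepair.containers import ClinicalTable, ExpressionMatrix, MarkerSet
from gcrepair.markers import combine_target, correlate_genes, select_markers
from gcrepair.risk import classify_risk, fit_hr_lr, ssa_nhej_score
from gcrepair.ssgsea import ssgsea_matrix
from gcrepair.synthetic import CohortParams, generate_cohort, generate_gene_sets

DEFAULT_SEED = 17

TARGET_TERMS = ["SSA_LIKE", "NHEJ_LIKE_POSREG", "NHEJ_LIKE_REG"]

# reduced sizes for replicate-heavy calibration tests
SMALL_PARAMS = dict(n_tumor=150, n_normal=15, n_genes=200, n_pos_program=20,
                    n_neg_program=20, n_low_genes=20, n_cgi_clusters=5,
                    n_sea_clusters=5, mut_intercept=float(np.log(2.0)))


@pytest.fixture(scope="session")
def cohort():
    """The default synthetic cohort (study conditions, seed 17)."""
    return generate_cohort(CohortParams(), seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def processed(cohort):
    """The cohort run through the full analysis once (shared downstream).

    Keys: expr (log2, imputed), clin (10-day filter applied), tumors,
    gene_sets, scores (ssGSEA), target, corr, markers, model, score
    (per-sample SSA-NHEJ score), risk (tumor risk classes).
    """
    expr = prep.filter_low_expressed(cohort.expression)
    expr = prep.mask_zeros(expr)
    expr = prep.knn_impute(expr, k=10)
    expr = prep.log2_transform(expr)
    clin = prep.filter_clinical(cohort.clinical)
    tumors = [s for s in expr.sample_ids
              if s in clin.df.index and clin.df.loc[s, "tissue"] == "tumor"]
    gene_sets = generate_gene_sets(cohort.truth)
    scores = ssgsea_matrix(expr, gene_sets)
    target = combine_target(scores.scores.loc[TARGET_TERMS, tumors])
    corr = correlate_genes(expr.subset_samples(tumors), target)
    markers = select_markers(corr)
    model = fit_hr_lr(expr.subset_samples(tumors), markers)
    score = ssa_nhej_score(expr, markers)
    risk = classify_risk(score.loc[tumors], model)
    return dict(expr=expr, clin=clin, tumors=tumors, gene_sets=gene_sets,
                scores=scores, target=target, corr=corr, markers=markers,
                model=model, score=score, risk=risk)


@pytest.fixture
def tiny_expr():
    """3 genes x 4 samples, log scale."""
    vals = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [4.0, 3.0, 2.0, 1.0],
         [2.0, 2.0, 2.0, 2.0]],
        index=["GA", "GB", "GC"], columns=["S1", "S2", "S3", "S4"])
    return ExpressionMatrix(vals, log_transformed=True)


@pytest.fixture
def small_markers():
    return MarkerSet(name="toy", positive_genes=["P1", "P2", "P3"],
                     negative_genes=["N1", "N2", "N3"])


def make_clinical(times, events, tissue="tumor", stage=None,
                  rfs_times=None, rfs_events=None, prefix="S"):
    """Build a minimal clinical table from parallel lists."""
    n = len(times)
    idx = [f"{prefix}{i + 1}" for i in range(n)]
    df = pd.DataFrame({
        "os_days": times,
        "os_event": events,
        "rfs_days": rfs_times if rfs_times is not None else np.nan,
        "rfs_event": rfs_events if rfs_events is not None else np.nan,
        "stage": stage if stage is not None else "NA",
        "age": 60.0,
        "sex": "male",
        "tissue": tissue,
    }, index=idx)
    return ClinicalTable(df)
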