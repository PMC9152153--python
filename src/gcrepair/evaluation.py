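"""Model evaluation: random-gene-set nulls, multivariate Cox adjustment,
the stage+risk decision tree, and Harrell's concordance index."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.utils import concordance_index as _ll_cindex

from .containers import ClinicalTable, ExpressionMatrix, GcRepairError, MarkerSet
from .risk import HIGH_RISK, LOW_RISK, roc_curve, ssa_nhej_score
from .survival import SurvivalFit, logrank_test, univariate_cox


@dataclass
class NullDistribution:
    """A metric's null distribution over random marker models."""

    metric: str                # cox_p_score | cox_p_class | logrank_p_class | auc
    values: np.ndarray         # one value per random model
    real_value: float
    empirical_p: float         # (1 + #{random at least as good}) / (n + 1)


SURVIVAL_METRICS = ("cox_p_score", "cox_p_class", "logrank_p_class")


def _survival_metrics(scores: pd.Series, clin: ClinicalTable,
                      endpoint: str,
                      which: tuple[str, ...] = SURVIVAL_METRICS
                      ) -> dict[str, float]:
    cutoff = float(np.median(scores.to_numpy()))
    classes = pd.Series(
        np.where(scores > cutoff, LOW_RISK, HIGH_RISK), index=scores.index)
    degenerate = classes.nunique() < 2
    out: dict[str, float] = {}
    for metric in which:
        if metric == "cox_p_score":
            try:
                out[metric] = univariate_cox(
                    scores.rename("score"), clin, endpoint).p_value
            except GcRepairError:
                out[metric] = 1.0
        elif metric == "cox_p_class":
            if degenerate:
                out[metric] = 1.0
                continue
            try:
                out[metric] = univariate_cox(
                    classes.rename("class"), clin, endpoint).p_value
            except GcRepairError:
                out[metric] = 1.0
        elif metric == "logrank_p_class":
            if degenerate:
                out[metric] = 1.0
                continue
            _, out[metric] = logrank_test(classes, clin, endpoint)
        else:
            raise GcRepairError(f"unknown survival metric {metric!r}")
    return out


def random_model_null(expr: ExpressionMatrix, markers: MarkerSet,
                      clin: ClinicalTable | None = None,
                      status: pd.Series | None = None,
                      n_pos: int | None = None, n_neg: int | None = None,
                      n_iter: int = 1000, seed: int = 0,
                      endpoint: str = "os",
                      method: str = "student",
                      exclude_real: bool = False,
                      survival_metrics: tuple[str, ...] = SURVIVAL_METRICS
                      ) -> dict[str, NullDistribution]:
    """Compare the real marker model against models built from random genes.

    Each iteration draws ``n_pos + n_neg`` distinct genes uniformly without
    replacement (the real markers are *not* excluded unless asked), labels
    the first ``n_pos`` positive, and runs the identical
    score/median-cutoff/classify pipeline.  With ``clin`` the survival
    metrics (Cox p of the score, Cox p and log-rank p of the class) are
    recorded; with ``status`` (tumor|normal labels) the ROC AUC is.
    The empirical p uses the add-one convention
    (1 + #{random at least as favourable}) / (n_iter + 1).
    """
    if clin is None and status is None:
        raise GcRepairError("provide clinical data and/or status labels")
    n_pos = n_pos if n_pos is not None else len(markers.positive_genes)
    n_neg = n_neg if n_neg is not None else len(markers.negative_genes)
    universe = list(expr.values.index)
    if exclude_real:
        real = set(markers.positive_genes) | set(markers.negative_genes)
        universe = [g for g in universe if g not in real]
    if n_pos + n_neg > len(universe):
        raise GcRepairError(
            f"cannot draw {n_pos + n_neg} genes from a universe of "
            f"{len(universe)}")
    rng = np.random.default_rng(seed)

    real_scores = ssa_nhej_score(expr, markers, method=method)
    metrics: dict[str, list[float]] = {}
    real_vals: dict[str, float] = {}
    if clin is not None:
        tumor_ids = [s for s in real_scores.index
                     if s in clin.df.index
                     and clin.df.loc[s, "tissue"] == "tumor"]
        real_surv = _survival_metrics(real_scores.loc[tumor_ids],
                                      clin, endpoint, survival_metrics)
        real_vals.update(real_surv)
        for k in real_surv:
            metrics[k] = []
    if status is not None:
        real_vals["auc"] = roc_curve(real_scores, status).auc
        metrics["auc"] = []

    for _ in range(n_iter):
        drawn = rng.choice(len(universe), size=n_pos + n_neg, replace=False)
        gene_idx = [universe[i] for i in drawn]
        rand = MarkerSet(name="random",
                         positive_genes=list(gene_idx[:n_pos]),
                         negative_genes=list(gene_idx[n_pos:]))
        scores = ssa_nhej_score(expr, rand, method=method)
        if clin is not None:
            surv = _survival_metrics(scores.loc[tumor_ids], clin, endpoint,
                                      survival_metrics)
            for k, v in surv.items():
                metrics[k].append(v)
        if status is not None:
            metrics["auc"].append(roc_curve(scores, status).auc)

    out: dict[str, NullDistribution] = {}
    for k, vals in metrics.items():
        vals = np.asarray(vals, dtype=float)
        if k == "auc":          # larger is better
            k_ge = int((vals >= real_vals[k]).sum())
        else:                   # smaller p is better
            k_ge = int((vals <= real_vals[k]).sum())
        out[k] = NullDistribution(
            metric=k, values=vals, real_value=float(real_vals[k]),
            empirical_p=(1 + k_ge) / (n_iter + 1))
    return out


STAGE_DUMMIES = ("II", "III", "IV")


def multivariate_cox(covariates: pd.DataFrame, clin: ClinicalTable,
                     endpoint: str = "os") -> tuple[list[SurvivalFit], int]:
    """Joint Cox fit over a per-sample covariate table.

    Recognised columns: ``risk_class`` (reference high_risk), ``stage``
    (reference I, dummies II/III/IV), ``sex`` (reference male), plus any
    numeric columns used as-is.  Complete cases only; returns the
    per-covariate fits and the complete-case count.
    """
    time, event = clin.endpoint(endpoint)
    common = time.index.intersection(covariates.index)
    design = pd.DataFrame(index=common)
    for col in covariates.columns:
        x = covariates.loc[common, col]
        if col == "risk_class":
            design[f"risk_class[{LOW_RISK}]"] = (x == LOW_RISK).astype(float)
            design.loc[x.isna(), f"risk_class[{LOW_RISK}]"] = np.nan
        elif col == "stage":
            x = x.replace("NA", np.nan)
            for lvl in STAGE_DUMMIES:
                design[f"stage[{lvl}]"] = (x == lvl).astype(float)
                design.loc[x.isna(), f"stage[{lvl}]"] = np.nan
        elif col == "sex":
            design["sex[female]"] = (x == "female").astype(float)
            design.loc[x.isna(), "sex[female]"] = np.nan
        else:
            design[col] = pd.to_numeric(x, errors="raise")
    df = design.copy()
    df["time"] = time.loc[common]
    df["event"] = event.loc[common]
    df = df.dropna()
    if len(df) < 3:
        raise GcRepairError("too few complete cases for multivariate Cox")
    for col in design.columns:
        if df[col].nunique() < 2:
            raise GcRepairError(f"covariate {col!r} is constant among "
                                "complete cases")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise GcRepairError(
            f"multivariate Cox failed to converge (possible separation): "
            f"{exc}") from exc
    fits = [SurvivalFit(covariate=name,
                        hazard_ratio=float(row["exp(coef)"]),
                        coefficient=float(row["coef"]),
                        p_value=float(row["p"]),
                        n=len(df), endpoint=endpoint)
            for name, row in cph.summary.iterrows()]
    return fits, len(df)


DEFAULT_TREE_RULES = {
    (LOW_RISK, "I"): "low", (LOW_RISK, "II"): "low",
    (LOW_RISK, "III"): "moderate", (LOW_RISK, "IV"): "moderate",
    (HIGH_RISK, "I"): "moderate", (HIGH_RISK, "II"): "moderate",
    (HIGH_RISK, "III"): "high", (HIGH_RISK, "IV"): "high",
}
# stage unknown: fall back on risk alone
_NA_RULES = {LOW_RISK: "moderate", HIGH_RISK: "high"}


def decision_tree_stratify(risk_class: pd.Series, stage: pd.Series,
                           rules: dict | None = None) -> pd.DataFrame:
    """Three-level risk stratification from risk class and disease stage.

    Returns a frame with columns ``group`` ({low, moderate, high}) and
    ``stage_missing`` flagging samples classified on risk alone.
    """
    rules = rules or DEFAULT_TREE_RULES
    common = risk_class.index.intersection(stage.index)
    out = pd.DataFrame(index=common, columns=["group", "stage_missing"])
    for s in common:
        rc = risk_class.loc[s]
        if rc not in (LOW_RISK, HIGH_RISK):
            raise GcRepairError(f"unknown risk class {rc!r} for {s!r}")
        st = stage.loc[s]
        if pd.isna(st) or st == "NA":
            out.loc[s] = [_NA_RULES[rc], True]
            continue
        if (rc, st) not in rules:
            raise GcRepairError(f"unknown stage token {st!r} for {s!r}")
        out.loc[s] = [rules[(rc, st)], False]
    out["stage_missing"] = out["stage_missing"].astype(bool)
    return out


def concordance_index(linear_predictor: pd.Series,
                      clin: ClinicalTable, endpoint: str = "os") -> float:
    """Harrell's C with the convention that a *higher* predictor goes with
    *longer* survival; tied predictions count 0.5."""
    time, event = clin.endpoint(endpoint)
    common = time.index.intersection(linear_predictor.dropna().index)
    t = time.loc[common].to_numpy(dtype=float)
    e = event.loc[common].to_numpy(dtype=int)
    x = linear_predictor.loc[common].to_numpy(dtype=float)
    if e.sum() == 0 or len(common) < 2:
        raise GcRepairError("no comparable pairs for the concordance index")
    try:
        return float(_ll_cindex(t, x, e))
    except ZeroDivisionError as exc:
        raise GcRepairError("no comparable pairs for the concordance "
                            "index") from exc
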