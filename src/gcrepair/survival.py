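"""Survival statistics: Cox screening, log-rank tests, Kaplan-Meier tables,
gene-set score screening and two-group rank-sum comparisons.

Model fitting is delegated to ``lifelines`` (Cox partial likelihood with
Breslow tie handling, Kaplan-Meier product-limit, log-rank chi-square);
this module owns the screening logic, alignment checks and conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.stats import mannwhitneyu

from .containers import ClinicalTable, GcRepairError
from .ssgsea import GeneSetScoreMatrix


@dataclass
class SurvivalFit:
    """Univariate (or one row of a multivariate) Cox fit."""

    covariate: str
    hazard_ratio: float
    coefficient: float
    p_value: float
    n: int
    endpoint: str


def _cox_frame(covariate: pd.Series, clin: ClinicalTable,
               endpoint: str) -> tuple[pd.DataFrame, str]:
    time, event = clin.endpoint(endpoint)
    common = time.index.intersection(covariate.index)
    x = covariate.loc[common]
    if x.dtype == object or isinstance(x.dtype, pd.CategoricalDtype):
        levels = sorted(pd.unique(x.dropna()))
        if len(levels) != 2:
            raise GcRepairError(
                f"label covariate must have exactly 2 levels, got {levels}")
        # reference = first sorted level; the fitted coefficient belongs to
        # the second level
        name = f"{covariate.name or 'covariate'}[{levels[1]}]"
        x = (x == levels[1]).astype(float).rename(name)
    else:
        x = x.astype(float)
        name = str(covariate.name or "covariate")
        x = x.rename(name)
    df = pd.DataFrame({"time": time.loc[common], "event": event.loc[common],
                       name: x}).dropna()
    return df, name


def univariate_cox(covariate: pd.Series, clin: ClinicalTable,
                   endpoint: str = "os") -> SurvivalFit:
    """Single-covariate Cox proportional-hazards fit (Breslow ties).

    ``covariate`` may be numeric or a 2-level label (the second sorted level
    is coded 1).  Returns the hazard ratio exp(coef) and the Wald p-value.
    """
    df, name = _cox_frame(covariate, clin, endpoint)
    if df["event"].sum() < 2:
        raise GcRepairError("univariate Cox needs at least 2 events")
    if df[name].nunique() < 2:
        raise GcRepairError(f"covariate {name!r} is constant")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise GcRepairError(f"Cox fit failed to converge: {exc}") from exc
    row = cph.summary.loc[name]
    return SurvivalFit(covariate=name,
                       hazard_ratio=float(row["exp(coef)"]),
                       coefficient=float(row["coef"]),
                       p_value=float(row["p"]),
                       n=len(df), endpoint=endpoint)


def logrank_test(groups: pd.Series, clin: ClinicalTable,
                 endpoint: str = "os") -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    time, event = clin.endpoint(endpoint)
    common = time.index.intersection(groups.dropna().index)
    g = groups.loc[common]
    levels = sorted(pd.unique(g))
    if len(levels) != 2:
        raise GcRepairError(f"log-rank needs exactly 2 non-empty groups, "
                            f"got {levels}")
    a = common[g == levels[0]]
    b = common[g == levels[1]]
    if event.loc[common].sum() < 1:
        raise GcRepairError("log-rank needs at least one event")
    res = _ll_logrank(time.loc[a], time.loc[b],
                      event_observed_A=event.loc[a],
                      event_observed_B=event.loc[b])
    return float(res.test_statistic), float(res.p_value)


def km_curve(groups: pd.Series, clin: ClinicalTable,
             endpoint: str = "os") -> dict[str, pd.DataFrame]:
    """Kaplan-Meier product-limit estimate per group.

    Returns, for each group label, a step-function table with columns
    ``time``, ``at_risk``, ``events`` and ``survival`` (rows at distinct
    observed times, survival non-increasing, S(0) = 1).
    """
    time, event = clin.endpoint(endpoint)
    common = time.index.intersection(groups.dropna().index)
    out: dict[str, pd.DataFrame] = {}
    for level in sorted(pd.unique(groups.loc[common])):
        members = common[groups.loc[common] == level]
        if len(members) == 0:
            raise GcRepairError(f"empty group {level!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(time.loc[members], event.loc[members])
        tbl = kmf.event_table
        surv = kmf.survival_function_["KM_estimate"]
        out[str(level)] = pd.DataFrame({
            "time": tbl.index.to_numpy(dtype=float),
            "at_risk": tbl["at_risk"].to_numpy(dtype=int),
            "events": tbl["observed"].to_numpy(dtype=int),
            "survival": surv.reindex(tbl.index).to_numpy(dtype=float),
        }).reset_index(drop=True)
    return out


def screen_gene_sets(scores: GeneSetScoreMatrix, clin: ClinicalTable,
                     endpoint: str = "os") -> pd.DataFrame:
    """Prognostic screen of gene-set scores.

    Per set: univariate Cox on the continuous score plus a log-rank test at
    the median split.  Constant score rows are flagged and excluded from
    ranking.  The table is sorted by Cox p ascending with name-order tie
    break.
    """
    sample_ids = scores.scores.columns
    missing = set(sample_ids) - set(clin.sample_ids)
    if missing:
        raise GcRepairError(
            f"score samples absent from clinical table: "
            f"{sorted(missing)[:5]}")
    rows = []
    for name, row in scores.scores.iterrows():
        if row.nunique() < 2:
            rows.append({"set": name, "hr": np.nan, "cox_p": np.nan,
                         "logrank_p": np.nan, "constant": True})
            continue
        fit = univariate_cox(row.rename(name), clin, endpoint)
        med = row.median()
        split = pd.Series(np.where(row > med, "above", "below"),
                          index=row.index)
        if split.nunique() < 2:  # degenerate split (mass at the median)
            lr_p = np.nan
        else:
            _, lr_p = logrank_test(split, clin, endpoint)
        rows.append({"set": name, "hr": fit.hazard_ratio,
                     "cox_p": fit.p_value, "logrank_p": lr_p,
                     "constant": False})
    table = pd.DataFrame(rows).set_index("set")
    ranked = table[~table["constant"]].sort_values(
        ["cox_p", "set"], kind="stable")
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    flagged = table[table["constant"]].copy()
    flagged["rank"] = np.nan
    return pd.concat([ranked, flagged])


def compare_groups(values: pd.Series,
                   labels: pd.Series) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) comparison of ``values``
    between the two groups in ``labels``.

    Uses the exact null distribution for small tie-free samples and the
    tie-corrected normal approximation otherwise.  Returns (U, p) where U
    counts pairs won by the first sorted group label.
    """
    common = values.index.intersection(labels.dropna().index)
    lab = labels.loc[common]
    levels = sorted(pd.unique(lab))
    if len(levels) != 2:
        raise GcRepairError(f"compare_groups needs exactly 2 groups, "
                            f"got {levels}")
    x = values.loc[common[lab == levels[0]]].dropna()
    y = values.loc[common[lab == levels[1]]].dropna()
    if len(x) == 0 or len(y) == 0:
        raise GcRepairError("both groups must be non-empty")
    res = mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)
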