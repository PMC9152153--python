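"""File-based pipeline chaining the analysis stages.

Each stage reads the outputs of its upstream stages from the working
directory and writes its own TSV/JSON results, so partial reruns are
possible and every artifact carries a provenance header (package version,
config hash, seed).  A missing upstream file is reported with the name of
the stage that should have produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import ClinicalTable, GcRepairError, MarkerSet
from . import io as gio
from . import preprocess as prep
from .ssgsea import ssgsea_matrix, GeneSetScoreMatrix
from .survival import screen_gene_sets, logrank_test, univariate_cox
from .markers import combine_target, correlate_genes, select_markers
from .risk import (classify_cancer_normal, classification_metrics,
                   classify_risk, fit_hr_lr, roc_curve, select_cutoff,
                   ssa_nhej_score)
from .mutations import compute_tmb, filter_nonsynonymous
from .methylation import (build_clusters, cluster_beta, hyper_hypo_scores,
                          relative_methylation)
from .evaluation import decision_tree_stratify, random_model_null
from .synthetic import CohortParams, generate_cohort, generate_gene_sets

log = logging.getLogger(__name__)

STAGES = ["simulate", "preprocess", "ssgsea", "screen", "select_markers",
          "fit", "score", "classify", "predict_status", "tmb", "methscore",
          "evaluate_null", "stratify"]

# stage -> files it must find (produced by an upstream stage)
_REQUIRES = {
    "preprocess": {"expression.tsv": "simulate",
                   "clinical.tsv": "simulate"},
    "ssgsea": {"expression_log2.tsv": "preprocess",
               "gene_sets.gmt": "simulate"},
    "screen": {"ssgsea_scores.tsv": "ssgsea",
               "clinical_filtered.tsv": "preprocess"},
    "select_markers": {"ssgsea_scores.tsv": "ssgsea",
                       "expression_log2.tsv": "preprocess",
                       "clinical_filtered.tsv": "preprocess"},
    "fit": {"markers.gmt": "select_markers",
            "expression_log2.tsv": "preprocess",
            "clinical_filtered.tsv": "preprocess"},
    "score": {"model.json": "fit", "expression_log2.tsv": "preprocess"},
    "classify": {"scores.tsv": "score", "model.json": "fit",
                 "clinical_filtered.tsv": "preprocess"},
    "predict_status": {"scores.tsv": "score", "model.json": "fit",
                       "clinical_filtered.tsv": "preprocess"},
    "tmb": {"mutations.maf.tsv": "simulate", "scores.tsv": "score"},
    "methscore": {"meth_beta.tsv": "simulate",
                  "meth_annotation.tsv": "simulate",
                  "clinical.tsv": "simulate"},
    "evaluate_null": {"expression_log2.tsv": "preprocess",
                      "markers.gmt": "select_markers",
                      "clinical_filtered.tsv": "preprocess",
                      "model.json": "fit"},
    "stratify": {"risk_classes.tsv": "classify",
                 "clinical_filtered.tsv": "preprocess"},
}

DEFAULT_CONFIG = {
    "seed": 17,
    "outdir": "gcrepair_run",
    "stages": STAGES,
    "params": {},                  # CohortParams overrides
    "max_zero_frac": 0.7,
    "knn_k": 10,
    "pseudocount": 1.0,
    "min_survival_days": 10.0,
    "alpha": 0.25,
    "normalize_ssgsea": False,
    "target_terms": ["SSA_LIKE", "NHEJ_LIKE_POSREG", "NHEJ_LIKE_REG"],
    "r_threshold": 0.4,
    "fdr": 0.001,
    "score_method": "student",
    "interrogated_mb": 38.0,
    "n_iter_null": 200,
    "endpoint": "os",
}


def _config_hash(cfg: dict) -> str:
    # the output location is not part of the scientific configuration
    cfg = {k: v for k, v in cfg.items() if k != "outdir"}
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _provenance(cfg: dict) -> list[str]:
    return [f"gcrepair {__version__} seed={cfg['seed']} "
            f"config={_config_hash(cfg)}"]


def _need(outdir: Path, stage: str) -> None:
    for fname, producer in _REQUIRES.get(stage, {}).items():
        if not (outdir / fname).exists():
            raise GcRepairError(
                f"stage {stage!r}: missing input {fname!r} "
                f"(produced by stage {producer!r})")


def _write_tsv(df: pd.DataFrame, path: Path, cfg: dict,
               index_label: str = "id") -> None:
    with open(path, "w") as fh:
        for line in _provenance(cfg):
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def _update_json(path: Path, updates: dict, cfg: dict) -> None:
    payload = {}
    if path.exists():
        payload = json.loads(path.read_text())
    payload.update(updates)
    payload["_provenance"] = _provenance(cfg)[0]
    path.write_text(json.dumps(payload, indent=2, default=float) + "\n")


def _tumor_ids(clin: ClinicalTable) -> list[str]:
    return list(clin.df.index[clin.df["tissue"] == "tumor"])


def _stage_simulate(outdir: Path, cfg: dict) -> None:
    params = CohortParams(**cfg["params"])
    cohort = generate_cohort(params, seed=cfg["seed"])
    gio.write_expression(cohort.expression, outdir / "expression.tsv",
                         header_lines=_provenance(cfg))
    gio.write_clinical(cohort.clinical, outdir / "clinical.tsv")
    gio.write_maf(cohort.mutations, outdir / "mutations.maf.tsv")
    gio.write_methylation(cohort.methylation, outdir / "meth_beta.tsv",
                          outdir / "meth_annotation.tsv")
    gene_sets = generate_gene_sets(cohort.truth)
    gio.write_gmt(gene_sets, outdir / "gene_sets.gmt")
    truth = pd.DataFrame({"activity": cohort.truth.activity})
    _write_tsv(truth, outdir / "truth_activity.tsv", cfg, "sample_id")
    (outdir / "truth_genes.json").write_text(json.dumps({
        "pos_genes": cohort.truth.pos_genes,
        "neg_genes": cohort.truth.neg_genes}, indent=2) + "\n")


def _stage_preprocess(outdir: Path, cfg: dict) -> None:
    _need(outdir, "preprocess")
    expr = gio.read_expression(outdir / "expression.tsv")
    expr = prep.filter_low_expressed(expr, cfg["max_zero_frac"])
    expr = prep.mask_zeros(expr)
    expr = prep.knn_impute(expr, k=cfg["knn_k"])
    expr = prep.log2_transform(expr, pseudocount=cfg["pseudocount"])
    gio.write_expression(expr, outdir / "expression_log2.tsv",
                         header_lines=_provenance(cfg))
    clin = gio.read_clinical(outdir / "clinical.tsv")
    clin = prep.filter_clinical(clin, min_days=cfg["min_survival_days"])
    gio.write_clinical(clin, outdir / "clinical_filtered.tsv")


def _stage_ssgsea(outdir: Path, cfg: dict) -> None:
    _need(outdir, "ssgsea")
    expr = gio.read_expression(outdir / "expression_log2.tsv",
                               log_transformed=True)
    sets = gio.read_gmt(outdir / "gene_sets.gmt")
    scores = ssgsea_matrix(expr, sets, alpha=cfg["alpha"],
                           normalize=cfg["normalize_ssgsea"])
    _write_tsv(scores.scores, outdir / "ssgsea_scores.tsv", cfg, "set")


def _scores_from_file(outdir: Path, cfg: dict) -> GeneSetScoreMatrix:
    return GeneSetScoreMatrix(scores=_read_tsv(outdir / "ssgsea_scores.tsv"),
                              alpha=cfg["alpha"],
                              normalized=cfg["normalize_ssgsea"])


def _stage_screen(outdir: Path, cfg: dict) -> None:
    _need(outdir, "screen")
    scores = _scores_from_file(outdir, cfg)
    clin = gio.read_clinical(outdir / "clinical_filtered.tsv")
    tumors = _tumor_ids(clin)
    keep = [s for s in scores.scores.columns if s in tumors]
    scores.scores = scores.scores[keep]
    table = screen_gene_sets(scores, clin, endpoint=cfg["endpoint"])
    _write_tsv(table, outdir / "screen_table.tsv", cfg, "set")


def _stage_select_markers(outdir: Path, cfg: dict) -> None:
    _need(outdir, "select_markers")
    score_rows = _read_tsv(outdir / "ssgsea_scores.tsv")
    expr = gio.read_expression(outdir / "expression_log2.tsv",
                               log_transformed=True)
    clin = gio.read_clinical(outdir / "clinical_filtered.tsv")
    tumors = [s for s in expr.sample_ids if s in _tumor_ids(clin)]
    missing = [t for t in cfg["target_terms"] if t not in score_rows.index]
    if missing:
        raise GcRepairError(f"target terms not in score matrix: {missing}")
    target = combine_target(score_rows.loc[cfg["target_terms"], tumors])
    corr = correlate_genes(expr.subset_samples(tumors), target)
    _write_tsv(corr, outdir / "correlations.tsv", cfg, "gene")
    ms = select_markers(corr, r_threshold=cfg["r_threshold"],
                        fdr=cfg["fdr"], name="selected")
    _write_marker_gmt(ms, outdir / "markers.gmt")


def _write_marker_gmt(ms: MarkerSet, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join([f"{ms.name}_POSITIVE", "na",
                            *ms.positive_genes]) + "\n")
        fh.write("\t".join([f"{ms.name}_NEGATIVE", "na",
                            *ms.negative_genes]) + "\n")


def _read_marker_gmt(path: Path) -> MarkerSet:
    pos, neg = gio.read_gmt(path)
    name = pos.name.rsplit("_POSITIVE", 1)[0]
    return MarkerSet(name=name, positive_genes=pos.genes,
                     negative_genes=neg.genes)


def _stage_fit(outdir: Path, cfg: dict) -> None:
    _need(outdir, "fit")
    markers = _read_marker_gmt(outdir / "markers.gmt")
    expr = gio.read_expression(outdir / "expression_log2.tsv",
                               log_transformed=True)
    clin = gio.read_clinical(outdir / "clinical_filtered.tsv")
    tumors = [s for s in expr.sample_ids if s in _tumor_ids(clin)]
    model = fit_hr_lr(expr.subset_samples(tumors), markers,
                      method=cfg["score_method"],
                      provenance={"seed": cfg["seed"]})
    # calibrate the tumor/normal cutoff on all samples with known tissue
    scored = ssa_nhej_score(expr, markers, method=cfg["score_method"])
    tissue = clin.df["tissue"].reindex(scored.index).dropna()
    if tissue.nunique() == 2:
        roc = roc_curve(scored.loc[tissue.index], tissue)
        model.cancer_normal_cutoff = select_cutoff(roc)
        model.provenance["cancer_normal_auc"] = roc.auc
    gio.save_model(model, outdir / "model.json")


def _stage_score(outdir: Path, cfg: dict) -> None:
    _need(outdir, "score")
    model = gio.load_model(outdir / "model.json")
    expr = gio.read_expression(outdir / "expression_log2.tsv",
                               log_transformed=True)
    scores = ssa_nhej_score(expr, model.marker_set,
                            method=model.score_method)
    _write_tsv(scores.to_frame(), outdir / "scores.tsv", cfg, "sample_id")


def _stage_classify(outdir: Path, cfg: dict) -> None:
    _need(outdir, "classify")
    model = gio.load_model(outdir / "model.json")
    scores = _read_tsv(outdir / "scores.tsv")["ssa_nhej_score"]
    clin = gio.read_clinical(outdir / "clinical_filtered.tsv")
    tumors = [s for s in scores.index if s in _tumor_ids(clin)]
    classes = classify_risk(scores.loc[tumors], model)
    _write_tsv(classes.to_frame(), outdir / "risk_classes.tsv", cfg,
               "sample_id")
    stat, p = logrank_test(classes, clin, endpoint=cfg["endpoint"])
    fit = univariate_cox(classes.rename("risk"), clin,
                         endpoint=cfg["endpoint"])
    _update_json(outdir / "metrics.json", {
        "risk_logrank_chi2": stat, "risk_logrank_p": p,
        "low_risk_hr": fit.hazard_ratio, "low_risk_cox_p": fit.p_value,
    }, cfg)


def _stage_predict_status(outdir: Path, cfg: dict) -> None:
    _need(outdir, "predict_status")
    model = gio.load_model(outdir / "model.json")
    if model.cancer_normal_cutoff is None:
        raise GcRepairError("stage 'predict_status': model has no "
                            "tumor/normal cutoff (stage 'fit' could not "
                            "calibrate one)")
    scores = _read_tsv(outdir / "scores.tsv")["ssa_nhej_score"]
    clin = gio.read_clinical(outdir / "clinical_filtered.tsv")
    truth = clin.df["tissue"].reindex(scores.index).dropna()
    pred = classify_cancer_normal(scores, model.cancer_normal_cutoff)
    _write_tsv(pred.to_frame(), outdir / "status_calls.tsv", cfg,
               "sample_id")
    m = classification_metrics(pred.loc[truth.index], truth)
    roc = roc_curve(scores.loc[truth.index], truth)
    _update_json(outdir / "metrics.json", {
        "cancer_normal_auc": roc.auc, "cancer_normal_tpr": m.tpr,
        "cancer_normal_specificity": m.specificity,
        "cancer_normal_accuracy": m.accuracy,
        "cancer_normal_precision": m.precision,
        "cancer_normal_f_measure": m.f_measure,
    }, cfg)


def _stage_tmb(outdir: Path, cfg: dict) -> None:
    _need(outdir, "tmb")
    muts = gio.read_maf(outdir / "mutations.maf.tsv")
    scores = _read_tsv(outdir / "scores.tsv")["ssa_nhej_score"]
    nonsyn = filter_nonsynonymous(muts)
    roster = sorted(set(muts.df["sample_id"]))
    tmb = compute_tmb(nonsyn, interrogated_mb=cfg["interrogated_mb"],
                      sample_roster=roster)
    _write_tsv(tmb.to_frame(), outdir / "tmb.tsv", cfg, "sample_id")
    common = tmb.index.intersection(scores.index)
    rho = float(pd.Series(tmb.loc[common]).corr(scores.loc[common],
                                                method="spearman"))
    _update_json(outdir / "metrics.json", {"tmb_score_spearman": rho}, cfg)


def _stage_methscore(outdir: Path, cfg: dict) -> None:
    _need(outdir, "methscore")
    meth = gio.read_methylation(outdir / "meth_beta.tsv",
                                outdir / "meth_annotation.tsv")
    clin = gio.read_clinical(outdir / "clinical.tsv")
    clusters = build_clusters(meth.annotation)
    cb = cluster_beta(meth, clusters)
    tumor = [s for s in cb.columns if s in _tumor_ids(clin)]
    normal = [s for s in cb.columns if s not in tumor]
    rel, _ = relative_methylation(cb[tumor], cb[normal])
    scores = hyper_hypo_scores(rel, clusters)
    _write_tsv(scores, outdir / "methscores.tsv", cfg, "sample_id")


def _stage_evaluate_null(outdir: Path, cfg: dict) -> None:
    _need(outdir, "evaluate_null")
    expr = gio.read_expression(outdir / "expression_log2.tsv",
                               log_transformed=True)
    markers = _read_marker_gmt(outdir / "markers.gmt")
    clin = gio.read_clinical(outdir / "clinical_filtered.tsv")
    status = clin.df["tissue"]
    nulls = random_model_null(
        expr, markers, clin=clin, status=status,
        n_iter=cfg["n_iter_null"], seed=cfg["seed"] + 1,
        endpoint=cfg["endpoint"], method=cfg["score_method"])
    _update_json(outdir / "null_metrics.json", {
        k: {"real_value": nd.real_value, "empirical_p": nd.empirical_p,
            "n_iter": len(nd.values)}
        for k, nd in nulls.items()}, cfg)


def _stage_stratify(outdir: Path, cfg: dict) -> None:
    _need(outdir, "stratify")
    classes = _read_tsv(outdir / "risk_classes.tsv")["risk_class"]
    clin = gio.read_clinical(outdir / "clinical_filtered.tsv")
    stage = clin.df["stage"].reindex(classes.index)
    strata = decision_tree_stratify(classes, stage)
    _write_tsv(strata, outdir / "strata.tsv", cfg, "sample_id")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "ssgsea": _stage_ssgsea,
    "screen": _stage_screen,
    "select_markers": _stage_select_markers,
    "fit": _stage_fit,
    "score": _stage_score,
    "classify": _stage_classify,
    "predict_status": _stage_predict_status,
    "tmb": _stage_tmb,
    "methscore": _stage_methscore,
    "evaluate_null": _stage_evaluate_null,
    "stratify": _stage_stratify,
}


def run_pipeline(config: dict | None = None) -> Path:
    """Run the configured stages in dependency order; returns the output
    directory.  Unknown stages and missing upstream files fail before any
    work is done."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    unknown = [s for s in cfg["stages"] if s not in STAGES]
    if unknown:
        raise GcRepairError(f"unknown stage(s): {unknown}")
    stages = [s for s in STAGES if s in cfg["stages"]]  # dependency order
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    # fail fast: every stage must find its inputs either on disk already or
    # among the stages scheduled before it
    planned: set[str] = set()
    for s in stages:
        for fname, producer in _REQUIRES.get(s, {}).items():
            if producer not in planned and not (outdir / fname).exists():
                raise GcRepairError(
                    f"stage {s!r}: missing input {fname!r} (produced by "
                    f"stage {producer!r}, which is not scheduled)")
        planned.add(s)
    for s in stages:
        log.info("running stage %s", s)
        _STAGE_FUNCS[s](outdir, cfg)
    return outdir
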