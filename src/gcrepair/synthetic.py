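"""Synthetic gastric-cancer cohort generator.

Every sample carries a latent DNA-repair activity ``a_i`` on a
standard-normal scale (tumors shifted up by ``delta_tumor``).  The activity
drives everything the analysis is supposed to detect:

* expression — a positive gene program rises with ``a_i`` and a negative
  program falls with it, on top of gene baselines and Gaussian noise
  (raw values are FPKM-like, ``2**signal - 1``);
* survival — exponential event times with hazard ``lambda0 * exp(-beta*a)``
  (higher activity is protective) and independent exponential censoring
  tuned to roughly 50% events;
* mutations — per-sample counts Poisson(exp(c0 + c1*a)), with about a
  quarter of records in synonymous/non-coding classes;
* methylation — CpG-island cluster betas shift up and open-sea cluster
  betas shift down with ``a_i`` on the logit scale.

The tumor-normal activity gap ``delta_tumor`` defaults to 2.2 so that a
monotone score of the activity separates tumors from normals with a
theoretical AUC of Phi(2.2/sqrt(2)) ~= 0.94, inside the 0.86-0.95 range the
scoring approach achieves on real cohorts; see docs/methods.md.

All draws come from a single seeded generator, so (params, seed) fully
determine every output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (ClinicalTable, ExpressionMatrix, GcRepairError,
                         GeneSet, MethylationData, MutationTable)


@dataclass(frozen=True)
class CohortParams:
    n_tumor: int = 300
    n_normal: int = 30
    n_genes: int = 2000
    n_pos_program: int = 30
    n_neg_program: int = 30
    delta_tumor: float = 2.2        # tumor shift of the latent activity
    beta_os: float = 0.8            # protective log-hazard coefficient
    beta_rfs: float = 0.8
    noise_sd: float = 1.0           # per-gene expression noise (log2 scale)
    baseline_hazard_os: float = 1.0 / 1000.0   # events per day at a=0
    baseline_hazard_rfs: float = 1.0 / 800.0
    mut_intercept: float = float(np.log(25.0))  # log mean mutation count
    mut_slope: float = 0.5
    meth_effect: float = 0.5        # logit-scale shift per unit activity
    n_cgi_clusters: int = 35
    n_sea_clusters: int = 35
    n_low_genes: int = 80           # zero-inflated genes for the filter
    sparse_zero_rate: float = 0.002  # extra scattered zeros -> imputation
    weight_range: tuple[float, float] = (0.5, 1.0)
    baseline_range: tuple[float, float] = (3.0, 8.0)

    def validate(self) -> None:
        if self.n_tumor < 2 or self.n_normal < 0 or self.n_genes < 10:
            raise GcRepairError("cohort sizes out of range")
        reserved = self.n_pos_program + self.n_neg_program + self.n_low_genes
        if reserved > self.n_genes:
            raise GcRepairError(
                f"program + low-expression genes ({reserved}) exceed "
                f"n_genes ({self.n_genes})")
        if self.noise_sd <= 0 or self.meth_effect < 0:
            raise GcRepairError("noise_sd must be > 0 and meth_effect >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a generated cohort."""

    activity: pd.Series            # latent a_i per sample
    pos_genes: list[str]
    neg_genes: list[str]
    gene_weights: pd.Series        # w_g for program genes
    beta_os: float
    mut_slope: float
    meth_effect: float
    params: CohortParams
    seed: int


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix   # raw FPKM-like scale
    clinical: ClinicalTable
    mutations: MutationTable
    methylation: MethylationData
    truth: SyntheticTruth


_VARIANT_CLASSES = [
    ("Missense_Mutation", 0.54), ("Silent", 0.18),
    ("Nonsense_Mutation", 0.06), ("Splice_Site", 0.04),
    ("Frame_Shift_Del", 0.04), ("Frame_Shift_Ins", 0.03),
    ("In_Frame_Del", 0.02), ("In_Frame_Ins", 0.01),
    ("Intron", 0.04), ("3'UTR", 0.03), ("5'UTR", 0.01),
]
_SNV_LIKE = {"Missense_Mutation", "Silent", "Nonsense_Mutation",
             "Splice_Site", "Intron", "3'UTR", "5'UTR"}
# pyrimidine-reference substitution spectrum, C>T dominant as in most
# solid tumors
_SUB_CLASSES = [("C", "T", 0.34), ("C", "A", 0.12), ("C", "G", 0.10),
                ("T", "C", 0.22), ("T", "A", 0.10), ("T", "G", 0.12)]
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(params: CohortParams | None = None,
                    seed: int = 17) -> SyntheticCohort:
    """Generate one cohort; bit-identical for identical (params, seed)."""
    params = params or CohortParams()
    params.validate()
    rng = np.random.default_rng(seed)
    p = params

    tumor_ids = [f"T{i + 1:04d}" for i in range(p.n_tumor)]
    normal_ids = [f"N{i + 1:04d}" for i in range(p.n_normal)]
    sample_ids = tumor_ids + normal_ids
    gene_ids = [f"G{i + 1:05d}" for i in range(p.n_genes)]

    # latent activity: normals ~ N(0,1), tumors ~ N(delta, 1)
    a = np.concatenate([
        rng.normal(p.delta_tumor, 1.0, size=p.n_tumor),
        rng.normal(0.0, 1.0, size=p.n_normal),
    ])
    activity = pd.Series(a, index=sample_ids, name="activity")

    # --- expression -------------------------------------------------------
    picked = rng.choice(p.n_genes,
                        size=p.n_pos_program + p.n_neg_program + p.n_low_genes,
                        replace=False)
    pos_idx = picked[:p.n_pos_program]
    neg_idx = picked[p.n_pos_program:p.n_pos_program + p.n_neg_program]
    low_idx = picked[p.n_pos_program + p.n_neg_program:]
    pos_genes = [gene_ids[i] for i in pos_idx]
    neg_genes = [gene_ids[i] for i in neg_idx]

    mu = rng.uniform(*p.baseline_range, size=p.n_genes)
    w = np.zeros(p.n_genes)
    w[pos_idx] = rng.uniform(*p.weight_range, size=p.n_pos_program)
    w[neg_idx] = -rng.uniform(*p.weight_range, size=p.n_neg_program)

    signal = mu[:, None] + w[:, None] * a[None, :]
    log2_expr = signal + rng.normal(0.0, p.noise_sd,
                                    size=(p.n_genes, len(sample_ids)))
    raw = np.clip(np.exp2(log2_expr) - 1.0, 0.0, None)

    # zero-inflated genes around the filter threshold
    zero_prob = rng.uniform(0.55, 0.95, size=p.n_low_genes)
    for k, gi in enumerate(low_idx):
        raw[gi, rng.random(len(sample_ids)) < zero_prob[k]] = 0.0
    # scattered dropout zeros among untouched background genes
    background = np.setdiff1d(np.arange(p.n_genes), picked)
    drop = rng.random((len(background), len(sample_ids))) < p.sparse_zero_rate
    for row, gi in enumerate(background):
        raw[gi, drop[row]] = 0.0

    expression = ExpressionMatrix(
        pd.DataFrame(raw, index=gene_ids, columns=sample_ids),
        log_transformed=False)

    # --- clinical ---------------------------------------------------------
    a_t = a[:p.n_tumor]
    haz_os = p.baseline_hazard_os * np.exp(-p.beta_os * a_t)
    t_os = rng.exponential(1.0 / haz_os)
    cens_rate_os = p.baseline_hazard_os * np.exp(-p.beta_os * p.delta_tumor)
    c_os = rng.exponential(1.0 / cens_rate_os, size=p.n_tumor)
    os_days = np.minimum(t_os, c_os)
    os_event = (t_os <= c_os).astype(int)

    haz_rfs = p.baseline_hazard_rfs * np.exp(-p.beta_rfs * a_t)
    t_rfs = rng.exponential(1.0 / haz_rfs)
    cens_rate_rfs = p.baseline_hazard_rfs * np.exp(
        -p.beta_rfs * p.delta_tumor)
    c_rfs = rng.exponential(1.0 / cens_rate_rfs, size=p.n_tumor)
    rfs_days = np.minimum(t_rfs, c_rfs)
    rfs_event = (t_rfs <= c_rfs).astype(int)

    stage_latent = -a_t + rng.normal(0.0, 1.0, size=p.n_tumor)
    qs = np.quantile(stage_latent, [0.25, 0.5, 0.75])
    stage = np.array(["I", "II", "III", "IV"])[
        np.searchsorted(qs, stage_latent)]

    clin = pd.DataFrame({
        "os_days": np.round(os_days, 1),
        "os_event": os_event,
        "rfs_days": np.round(rfs_days, 1),
        "rfs_event": rfs_event,
        "stage": stage,
        "age": np.clip(np.round(rng.normal(65, 10, p.n_tumor)), 30, 90),
        "sex": rng.choice(["male", "female"], size=p.n_tumor),
        "tissue": "tumor",
    }, index=tumor_ids)
    clin_n = pd.DataFrame({
        "os_days": np.round(rng.uniform(500, 3000, p.n_normal), 1),
        "os_event": 0,
        "rfs_days": np.nan,
        "rfs_event": np.nan,
        "stage": "NA",
        "age": np.clip(np.round(rng.normal(60, 10, p.n_normal)), 30, 90),
        "sex": rng.choice(["male", "female"], size=p.n_normal),
        "tissue": "normal",
    }, index=normal_ids)
    clinical = ClinicalTable(pd.concat([clin, clin_n]))

    # --- mutations (tumors only) ------------------------------------------
    counts = rng.poisson(np.exp(p.mut_intercept + p.mut_slope * a_t))
    class_names = [c for c, _ in _VARIANT_CLASSES]
    class_probs = np.array([q for _, q in _VARIANT_CLASSES])
    sub_probs = np.array([q for *_, q in _SUB_CLASSES])
    records: dict[str, list] = {k: [] for k in
                                ("sample_id", "gene", "variant_classification",
                                 "chrom", "pos", "ref", "alt")}
    for sid, n_mut in zip(tumor_ids, counts):
        if n_mut == 0:
            continue
        vcs = rng.choice(class_names, size=n_mut, p=class_probs)
        genes = rng.choice(gene_ids, size=n_mut)
        chroms = rng.choice([str(c) for c in range(1, 23)], size=n_mut)
        poss = rng.integers(1, 50_000_000, size=n_mut)
        subs = rng.choice(len(_SUB_CLASSES), size=n_mut, p=sub_probs)
        flips = rng.random(n_mut) < 0.5
        for vc, g, ch, pos, sub_i, flip in zip(vcs, genes, chroms, poss,
                                               subs, flips):
            if vc in _SNV_LIKE:
                ref, alt, _ = _SUB_CLASSES[sub_i]
                if flip:  # record on the purine strand
                    ref, alt = _COMP[ref], _COMP[alt]
            elif "Del" in vc:
                ref, alt = "AC", "-"
            else:
                ref, alt = "-", "AC"
            records["sample_id"].append(sid)
            records["gene"].append(g)
            records["variant_classification"].append(vc)
            records["chrom"].append(ch)
            records["pos"].append(int(pos))
            records["ref"].append(ref)
            records["alt"].append(alt)
    mutations = MutationTable(pd.DataFrame(records))

    # --- methylation --------------------------------------------------------
    probe_rows = []
    beta_logits = []
    for kind, n_clusters in ((("CGI"), p.n_cgi_clusters),
                             (("open_sea"), p.n_sea_clusters)):
        for ci in range(n_clusters):
            chrom = f"chr{(ci % 5) + 1}"
            start = 10_000 + (ci // 5) * 50_000 + \
                (0 if kind == "CGI" else 25_000)
            n_probes = int(rng.integers(3, 7)) if kind == "CGI" \
                else int(rng.integers(2, 5))
            gaps = rng.integers(20, 250, size=n_probes - 1) if kind == "CGI" \
                else rng.integers(50, 450, size=n_probes - 1)
            positions = start + np.concatenate([[0], np.cumsum(gaps)])
            base = rng.normal(-2.0, 0.4) if kind == "CGI" \
                else rng.normal(1.2, 0.4)
            sens = rng.uniform(0.7, 1.3)
            direction = 1.0 if kind == "CGI" else -1.0
            shift = direction * p.meth_effect * sens * a  # per sample
            for j, pos in enumerate(positions):
                pid = f"cg_{kind}_{ci:03d}_{j}"
                promoter = bool(rng.random() < 0.8) if kind == "CGI" else False
                probe_rows.append((pid, chrom, int(pos), kind, promoter))
                probe_off = rng.normal(0.0, 0.2)
                noise = rng.normal(0.0, 0.3, size=len(sample_ids))
                beta_logits.append(base + probe_off + shift + noise)
    # a handful of probes outside both region classes (dropped by clustering)
    for j in range(12):
        pid = f"cg_other_{j:03d}"
        probe_rows.append((pid, "chr9", 10_000 + j * 10_000, "other", False))
        beta_logits.append(rng.normal(0.0, 1.0)
                           + rng.normal(0.0, 0.3, size=len(sample_ids)))
    annotation = pd.DataFrame(
        probe_rows,
        columns=["probe_id", "chrom", "pos", "region_class", "promoter"],
    ).set_index("probe_id")
    beta = pd.DataFrame(_sigmoid(np.vstack(beta_logits)),
                        index=annotation.index, columns=sample_ids)
    methylation = MethylationData(beta=beta, annotation=annotation)

    truth = SyntheticTruth(
        activity=activity,
        pos_genes=pos_genes, neg_genes=neg_genes,
        gene_weights=pd.Series(w[picked[:p.n_pos_program + p.n_neg_program]],
                               index=pos_genes + neg_genes),
        beta_os=p.beta_os, mut_slope=p.mut_slope,
        meth_effect=p.meth_effect, params=p, seed=seed)

    return SyntheticCohort(expression=expression, clinical=clinical,
                           mutations=mutations, methylation=methylation,
                           truth=truth)


def generate_gene_sets(truth: SyntheticTruth, seed: int | None = None,
                       set_size: int = 30, overlap: float = 0.7,
                       n_decoys: int = 20) -> list[GeneSet]:
    """Planted repair-like gene sets plus uniform decoys.

    Three planted sets mimic the SSA / NHEJ term structure: each draws
    ``overlap * set_size`` genes from the positive program and fills the
    rest with random background genes (overlap must stay >= 0.6 so the
    planted signal dominates).  Decoys are drawn uniformly from all genes.
    """
    if overlap < 0.6:
        raise GcRepairError("planted sets must overlap the positive "
                            "program by at least 60%")
    rng = np.random.default_rng(truth.seed + 101 if seed is None else seed)
    n_genes = truth.params.n_genes
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    program = set(truth.pos_genes)
    background = [g for g in gene_ids if g not in program]
    n_core = int(round(overlap * set_size))
    n_core = min(n_core, len(truth.pos_genes))
    sets = []
    for name in ("SSA_LIKE", "NHEJ_LIKE_POSREG", "NHEJ_LIKE_REG"):
        core = list(rng.choice(truth.pos_genes, size=n_core, replace=False))
        filler = list(rng.choice(background, size=set_size - n_core,
                                 replace=False))
        sets.append(GeneSet(name=name, genes=core + filler))
    for d in range(n_decoys):
        genes = list(rng.choice(gene_ids, size=set_size, replace=False))
        sets.append(GeneSet(name=f"DECOY_{d + 1:02d}", genes=genes))
    return sets
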