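# gcrepair

DNA-repair activity scoring and survival risk models for gastric-cancer
expression cohorts.

Error-prone double-strand-break (DSB) repair — single-strand annealing
(SSA) and nonhomologous end-joining (NHEJ) — is unusually informative about
outcome in gastric cancer: tumors with *higher* repair-program activity
accumulate more somatic mutations yet have *better* survival. `gcrepair`
packages that analysis for anyone who wants to score their own cohort or
study the statistical behaviour of the approach: it computes per-sample
gene-set activity (ssGSEA), selects marker genes that track that activity,
condenses them into a per-sample score, and calibrates two classifiers on
the score — a survival risk split and a tumor-vs-normal caller — plus the
supporting mutational-burden and DNA-methylation analyses.

## The score

Given a positive marker list *P* (genes rising with repair activity) and a
negative list *N* (genes falling with it), the **SSA-NHEJ score** of sample
*s* is the two-sample t statistic

    score(s) = t( {x_gs : g ∈ P},  {x_gs : g ∈ N} )

on log2 expression (pooled-variance Student t by default). The packaged
panel `GC-SSA-NHEJ-76` carries the published 37 positive + 39 negative
genes with its published cutoffs: training-median 3.46 for the high-risk /
low-risk survival split (`score > cutoff → low risk`) and 0.008 for the
tumor/normal call (`score ≥ cutoff → tumor`). For a new cohort both
cutoffs are re-fitted: the survival cutoff as the training-median score,
the tumor/normal cutoff by Youden's J on the ROC curve.

Because real gastric-cancer cohorts cannot be redistributed, the package
includes a first-class synthetic cohort generator
(`gcrepair.synthetic.generate_cohort`) that plants the full causal
structure the analysis assumes — a latent repair activity driving an
anticorrelated two-program expression signature, survival hazard,
mutation counts and CGI/open-sea methylation shifts — with recorded ground
truth, so every stage is testable offline. See `docs/methods.md` for the
model and its limits.

## Worked example

The numbered drivers under `analysis/` run the whole study on the default
synthetic cohort (seed 17) and share one results directory:

```bash
cd analysis
python 01_simulate_cohort.py      # 2000 genes x 330 samples (300 T / 30 N)
python 02_preprocess_expression.py
python 03_screen_repair_sets.py
python 04_select_markers.py
python 05_fit_risk_models.py
python 06_mutations_methylation.py
python 07_evaluate_models.py
```

Step 04 and 05 print, on that cohort:

```
selected 30 positive and 28 negative marker genes
planted-program recovery: 96.7% (58/60)
false selections: 0

survival cutoff (training median score): 7.107
tumor/normal cutoff (Youden): 4.227
risk split log-rank p (OS): 2.53e-13
low-risk hazard ratio: 0.292 (Cox p 4.36e-12)
cancer-normal AUC: 0.956, accuracy 0.855, F 0.913
```

Reading: marker selection recovered 58 of the 60 planted program genes
with no false picks; the median-split risk classes separate survival
strongly (low-risk hazard ratio well below 1, i.e. high repair activity is
protective); and the same score separates tumors from normals with AUC
0.956. Step 06 shows mutational burden rising with the score (Spearman
r = 0.93) and the methylation scores moving in opposite directions (CGI
hypermethylation up, open-sea hypomethylation down, |r| > 0.9), and step 07
shows the real panel beating 200 random 76-gene panels on every metric
(empirical p ≈ 0.005).

The same chain is available as a library call
(`gcrepair.pipeline.run_pipeline`) and as a CLI
(`gcrepair run -c config.yaml`, with per-stage subcommands such as
`gcrepair ssgsea`, `gcrepair score`, `gcrepair tmb`, `gcrepair methscore`).

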