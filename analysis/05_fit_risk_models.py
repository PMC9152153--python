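#!/usr/bin/env python
"""Fit the two classifiers and report their headline numbers.

Survival classifier: SSA-NHEJ score with the training-median cutoff (high
score -> low risk).  Tumor/normal classifier: same score with a
Youden-optimal ROC cutoff.
"""

import json

from common import parse_args
from gcrepair.io import load_model
from gcrepair.pipeline import run_pipeline

args = parse_args(__doc__)
out = run_pipeline({"seed": args.seed, "outdir": str(args.outdir),
                    "stages": ["fit", "score", "classify",
                               "predict_status"]})

model = load_model(out / "model.json")
metrics = json.loads((out / "metrics.json").read_text())
print(f"survival cutoff (training median score): "
      f"{model.survival_cutoff:.3f}")
print(f"tumor/normal cutoff (Youden): {model.cancer_normal_cutoff:.3f}")
print(f"risk split log-rank p (OS): {metrics['risk_logrank_p']:.3g}")
print(f"low-risk hazard ratio: {metrics['low_risk_hr']:.3f} "
      f"(Cox p {metrics['low_risk_cox_p']:.3g})")
print(f"cancer-normal AUC: {metrics['cancer_normal_auc']:.3f}, "
      f"accuracy {metrics['cancer_normal_accuracy']:.3f}, "
      f"F {metrics['cancer_normal_f_measure']:.3f}")
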