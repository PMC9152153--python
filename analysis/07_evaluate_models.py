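#!/usr/bin/env python
"""Evaluate the fitted models: random-gene-set null comparison and the
stage + risk decision-tree stratification."""

import json

import pandas as pd

from common import parse_args
from gcrepair.pipeline import run_pipeline

args = parse_args(__doc__)
out = run_pipeline({"seed": args.seed, "outdir": str(args.outdir),
                    "stages": ["evaluate_null", "stratify"]})

nulls = json.loads((out / "null_metrics.json").read_text())
for metric in ("cox_p_score", "cox_p_class", "logrank_p_class", "auc"):
    if metric in nulls:
        d = nulls[metric]
        print(f"{metric}: real={d['real_value']:.3g} "
              f"empirical p={d['empirical_p']:.3g} "
              f"({d['n_iter']} random models)")
strata = pd.read_csv(out / "strata.tsv", sep="\t", index_col=0,
                     comment="#")
print("decision-tree strata sizes:",
      strata["group"].value_counts().to_dict())
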