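#!/usr/bin/env python
"""Tumor mutational burden and methylation scores against the SSA-NHEJ
score: higher repair activity should mean more mutations, CGI gain and
open-sea loss."""

import json

import pandas as pd

from common import parse_args
from gcrepair.pipeline import run_pipeline

args = parse_args(__doc__)
out = run_pipeline({"seed": args.seed, "outdir": str(args.outdir),
                    "stages": ["tmb", "methscore"]})

metrics = json.loads((out / "metrics.json").read_text())
tmb = pd.read_csv(out / "tmb.tsv", sep="\t", index_col=0, comment="#")
hh = pd.read_csv(out / "methscores.tsv", sep="\t", index_col=0,
                 comment="#")
scores = pd.read_csv(out / "scores.tsv", sep="\t", index_col=0,
                     comment="#")["ssa_nhej_score"]
print(f"median TMB: {tmb['tmb'].median():.2f} mutations/Mb")
print(f"TMB vs SSA-NHEJ score Spearman r: "
      f"{metrics['tmb_score_spearman']:.3f}")
common_ids = hh.index.intersection(scores.index)
print(f"hyper-methylation score vs score r: "
      f"{hh.loc[common_ids, 'hyper_score'].corr(scores[common_ids]):.3f}")
print(f"hypo-methylation score vs score r: "
      f"{hh.loc[common_ids, 'hypo_score'].corr(scores[common_ids]):.3f}")
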