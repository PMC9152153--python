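#!/usr/bin/env python
"""Score every gene set per sample with ssGSEA and screen them for
prognostic value (univariate Cox on the score + log-rank at the median
split).  The planted repair-like sets should dominate the ranking."""

import pandas as pd

from common import parse_args
from gcrepair.pipeline import run_pipeline

args = parse_args(__doc__)
out = run_pipeline({"seed": args.seed, "outdir": str(args.outdir),
                    "stages": ["ssgsea", "screen"]})

table = pd.read_csv(out / "screen_table.tsv", sep="\t", index_col=0,
                    comment="#")
top = table.sort_values("rank").head(5)
print("top 5 gene sets by Cox p:")
print(top[["hr", "cox_p", "logrank_p", "rank"]].to_string())
planted = {"SSA_LIKE", "NHEJ_LIKE_POSREG", "NHEJ_LIKE_REG"}
print(f"planted sets in top 3: "
      f"{len(planted & set(top.index[:3]))} of 3")
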