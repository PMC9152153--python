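#!/usr/bin/env python
"""Apply the expression and clinical filters.

Genes that are zero in more than 70% of samples are dropped, remaining
zeros are KNN-imputed over gene neighbours, values are log2-transformed,
and patients who died within 10 days are excluded.
"""

import pandas as pd

from common import parse_args
from gcrepair.pipeline import run_pipeline

args = parse_args(__doc__)
out = run_pipeline({"seed": args.seed, "outdir": str(args.outdir),
                    "stages": ["preprocess"]})

raw = pd.read_csv(out / "expression.tsv", sep="\t", index_col=0,
                  comment="#")
kept = pd.read_csv(out / "expression_log2.tsv", sep="\t", index_col=0,
                   comment="#")
clin_all = pd.read_csv(out / "clinical.tsv", sep="\t", index_col=0,
                       comment="#")
clin = pd.read_csv(out / "clinical_filtered.tsv", sep="\t", index_col=0,
                   comment="#")
print(f"zero-fraction filter: {raw.shape[0]} -> {kept.shape[0]} genes")
print(f"10-day early-death exclusion: {len(clin_all)} -> {len(clin)} "
      "samples")
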