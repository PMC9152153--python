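#!/usr/bin/env python
"""Generate the synthetic gastric-cancer cohort used by all later steps.

Writes expression (raw FPKM-like), clinical, mutation, methylation and
gene-set files plus the recorded ground truth, then summarises the cohort.
"""

import pandas as pd

from common import parse_args
from gcrepair.pipeline import run_pipeline

args = parse_args(__doc__)
out = run_pipeline({"seed": args.seed, "outdir": str(args.outdir),
                    "stages": ["simulate"]})

clin = pd.read_csv(out / "clinical.tsv", sep="\t", index_col=0, comment="#")
expr_shape = pd.read_csv(out / "expression.tsv", sep="\t", index_col=0,
                         comment="#").shape
muts = pd.read_csv(out / "mutations.maf.tsv", sep="\t")
print(f"cohort written to {out}")
print(f"  expression: {expr_shape[0]} genes x {expr_shape[1]} samples")
print(f"  tissue: {clin['tissue'].value_counts().to_dict()}")
print(f"  OS events among tumors: "
      f"{int(clin.loc[clin.tissue == 'tumor', 'os_event'].sum())}")
print(f"  somatic mutation records: {len(muts)}")
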