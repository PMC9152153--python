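#!/usr/bin/env python
"""Select marker genes correlated with the combined repair-activity target
(|r| > 0.4, BH-FDR < 0.001) and compare them with the planted programs."""

import json

from common import parse_args
from gcrepair.pipeline import run_pipeline, _read_marker_gmt

args = parse_args(__doc__)
out = run_pipeline({"seed": args.seed, "outdir": str(args.outdir),
                    "stages": ["select_markers"]})

ms = _read_marker_gmt(out / "markers.gmt")
truth = json.loads((out / "truth_genes.json").read_text())
planted = set(truth["pos_genes"]) | set(truth["neg_genes"])
selected = set(ms.positive_genes) | set(ms.negative_genes)
print(f"selected {len(ms.positive_genes)} positive and "
      f"{len(ms.negative_genes)} negative marker genes")
print(f"planted-program recovery: "
      f"{100 * len(selected & planted) / len(planted):.1f}% "
      f"({len(selected & planted)}/{len(planted)})")
print(f"false selections: {len(selected - planted)}")
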