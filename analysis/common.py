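"""Shared plumbing for the numbered analysis drivers.

All drivers write into the same results directory so each step can pick up
the previous step's files; run them in order (01 .. 07).
"""

from __future__ import annotations

import argparse
from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results" / "cohort_run"


def parse_args(description: str) -> argparse.Namespace:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=17)
    ap.add_argument("--outdir", type=Path, default=RESULTS)
    return ap.parse_args()
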