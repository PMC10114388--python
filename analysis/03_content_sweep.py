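#!/usr/bin/env python
"""Run the full elastin-content sweep (ten contents x three load cases plus
the sheet model) and write the study tables:

  results/sweep/table2.csv      rotation stresses vs content
  results/sweep/fig5.csv        collagen stress/displacement/slopes vs content
  results/sweep/fig3_ratios.csv sheet-vs-fibre ratios at 14.4%

Heavy: ~50 large solves; expect roughly 20-30 minutes on one CPU.  Pass
--contents to run a subset, e.g. --contents 0 14.4 33.5
"""

import argparse
import logging
from pathlib import Path

from ligafem.sweep import StudyConfig, run_sweep

logging.basicConfig(level=logging.INFO, format="%(message)s")

parser = argparse.ArgumentParser()
parser.add_argument("--contents", type=float, nargs="*", default=None)
parser.add_argument("--out", type=Path,
                    default=Path(__file__).resolve().parents[1] / "results" / "sweep")
args = parser.parse_args()

cfg = StudyConfig()
if args.contents:
    cfg.contents_pct = tuple(args.contents)

sweep = run_sweep(cfg, out_dir=args.out, cache_dir=args.out / "cache")
print(sweep.table.to_string(index=False))
if sweep.partial:
    raise SystemExit("sweep incomplete; see FAILURES.json")
print(f"\ntables written under {args.out}")
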