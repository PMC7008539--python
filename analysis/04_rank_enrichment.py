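#!/usr/bin/env python
"""Test whether disease-genus models concentrate at the top of each
score-ranked list.

For MI, SGA and MR: rank the cohort, walk the running-sum statistic W
(+1/P at a disease model, -1/N otherwise), and calibrate max W against
10,000 label shuffles (null 1) and 10,000 genus-membership redraws
weighted by genus size (null 2).  Mann-Whitney compares score
distributions between disease and background models, BH-adjusted across
the three scores.

Reads results/scores.tsv (run 03 first); writes
results/enrichment_summary.tsv and per-score W curves.
"""

import sys
from pathlib import Path

import pandas as pd

from passengerscreen.pipeline import RunConfig, run_enrichment

ROOT = Path(__file__).resolve().parents[1]
SEED = 101


def main() -> None:
    scores_path = ROOT / "results" / "scores.tsv"
    if not scores_path.exists():
        sys.exit("run 03_score_models.py first")
    table = pd.read_csv(scores_path, sep="\t")
    cfg = RunConfig(out_dir=str(ROOT / "results"), seed=SEED)
    summary, _ = run_enrichment(table, cfg)
    print(summary.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    best = summary.loc[summary["max_W"].idxmax(), "score"]
    print(f"\nstrongest enrichment: {best} "
          f"(max W = {summary['max_W'].max():.4f})")
    print(f"wrote {ROOT / 'results' / 'enrichment_summary.tsv'}")


if __name__ == "__main__":
    main()
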