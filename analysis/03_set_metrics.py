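#!/usr/bin/env python
"""Similarity / suppression / novelty for every combined stress.

Writes results/run/metrics.tsv (36 rows: 18 combinations x 2 directions)
and prints the most suppressive and most novel combinations.
"""

from pathlib import Path

import pandas as pd

from stressatlas.pipeline import stage_metrics

RUN = Path(__file__).resolve().parents[1] / "results" / "run"

if __name__ == "__main__":
    stage_metrics(RUN)
    m = pd.read_csv(RUN / "metrics.tsv", sep="\t")
    up = m[m["direction"] == "up"]
    print("strongest suppression (|value|, up):")
    print(up.reindex(up["suppression"].abs().sort_values(ascending=False).index).head(3))
    print("most novel combined responses (up):")
    print(up.sort_values("novelty", ascending=False).head(3))
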