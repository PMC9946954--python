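#!/usr/bin/env python
"""Permutation-based pathway activity per condition, and robust bins.

1000 permutations per condition x direction; bins classified U / UD / D / N
and clustered by Jaccard distance.  Prints the class counts and the robust
bins per stress group.
"""

from pathlib import Path

import pandas as pd

from stressatlas.pipeline import stage_pathways

RUN = Path(__file__).resolve().parents[1] / "results" / "run"

if __name__ == "__main__":
    stage_pathways(RUN, n_perm=1000, seed=0)
    classes = pd.read_csv(RUN / "bin_classes.tsv", sep="\t", index_col=0)
    counts = classes.stack().value_counts()
    print("bin-activity classes over all condition x bin cells:")
    print(counts.to_string())
    robust = pd.read_csv(RUN / "robust_bins.tsv", sep="\t")
    print(f"{len(robust)} robust (stress group, bin, direction) entries")
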