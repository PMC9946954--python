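#!/usr/bin/env python
"""TF regulatory network: robust TFs, expected edges, cut-off optimization.

Identifies TFs responding consistently in >70% of a stress group, builds the
TF->TF network from the union GRN, classifies edges as expected/unexpected
from activator/repressor modes and expression directions, sweeps the
coefficient cut-off for the best expected-edge ratio, and links robust TFs
to the functional bins they control (>= 5% of bin genes).
"""

import json
from pathlib import Path

import pandas as pd

from stressatlas.pipeline import stage_tfrn

RUN = Path(__file__).resolve().parents[1] / "results" / "run"

if __name__ == "__main__":
    stage_tfrn(RUN)
    robust = pd.read_csv(RUN / "robust_tfs.tsv", sep="\t")
    print(f"{robust['tf'].nunique()} robustly-responding TFs "
          f"({len(robust)} TF x stress-group entries)")
    cutoff = json.loads((RUN / "cutoff.json").read_text())
    print("cut-off optimization:", cutoff)
    links = pd.read_csv(RUN / "tf_bin_links.tsv", sep="\t")
    if len(links):
        print("TF->bin link expectations:")
        print(links["expectation"].value_counts().to_string())
    else:
        print("no TF->bin links above the 5% control threshold")
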