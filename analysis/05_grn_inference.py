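#!/usr/bin/env python
"""Fit one ElasticNet model per modeling gene per dataset (7 stresses + ALL).

Cross-validated hyperparameter grids, R^2 > 0.8 quality filter, union of the
stress-specific networks, high-confidence one-TF-per-target extraction.
This is the slow step (~responses x 8 model fits).
"""

from pathlib import Path

import pandas as pd

from stressatlas.pipeline import stage_grn

RUN = Path(__file__).resolve().parents[1] / "results" / "run"

if __name__ == "__main__":
    stage_grn(RUN, seed=0)
    models = pd.read_csv(RUN / "models.tsv", sep="\t")
    union = pd.read_csv(RUN / "union_edges.tsv", sep="\t")
    hc = pd.read_csv(RUN / "hc_grn.tsv", sep="\t")
    print(f"{models[['dataset', 'target']].drop_duplicates().shape[0]} fitted models")
    print(f"union network: {len(union)} coefficient entries, "
          f"{union[['tf', 'target']].drop_duplicates().shape[0]} distinct edges")
    print("high-confidence GRN modes:")
    print(hc["mode"].value_counts().to_string())
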