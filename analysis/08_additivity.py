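#!/usr/bin/env python
"""The additive model of combined-stress expression and stress dominance.

9-category averaging per focal stress, global OLS of mean Sxy on mean Sx and
Sy, per-stress per-gene OLS, dominance ranking by the Sx coefficient, and
the higher/lower/within outcome classification.
"""

import json
from pathlib import Path

import pandas as pd

from stressatlas.additivity import assemble, classify_outcomes, condition_log2fc
from stressatlas.design import make_design
from stressatlas.io import read_degsets
from stressatlas.pipeline import load_de_tables, stage_additivity

RUN = Path(__file__).resolve().parents[1] / "results" / "run"

if __name__ == "__main__":
    stage_additivity(RUN, orientation="focal")
    gfit = json.loads((RUN / "global_fit.json").read_text())
    print(
        "global averaged fit: Sxy = "
        f"{gfit['b0']:.2f} + {gfit['bx']:.2f}*Sx + {gfit['by']:.2f}*Sy "
        f"(R^2 = {gfit['r2']:.2f}, MAE = {gfit['mae']:.2f}, RMSE = {gfit['rmse']:.2f})"
    )
    fits = pd.read_csv(RUN / "per_stress_fits.tsv", sep="\t")
    print(fits[["stress", "bx", "by", "r2"]].to_string(index=False))
    print("dominance ranking:", (RUN / "ranking.txt").read_text().strip())

    design = make_design()
    degsets = read_degsets(RUN / "degsets.json")
    lfc = condition_log2fc(load_de_tables(RUN), design.stress_conditions)
    long = assemble(lfc, degsets, design, orientation="focal")
    outcomes = classify_outcomes(long).value_counts()
    outcomes.to_csv(RUN / "outcomes.tsv", sep="\t")
    print("combined-stress outcomes:", outcomes.to_dict())
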