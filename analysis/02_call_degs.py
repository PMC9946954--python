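#!/usr/bin/env python
"""Call DEGs per contrast and consolidate across the two control batches.

A gene is differentially expressed in a condition only if BH-adjusted
p < 0.05 and |log2fc| > 1 against both controls.  Prints the per-condition
set sizes and the number of modeling genes (DEG in more than 5 conditions).
"""

import json
from pathlib import Path

from stressatlas.degs import modeling_genes
from stressatlas.io import read_degsets
from stressatlas.pipeline import stage_degs

RUN = Path(__file__).resolve().parents[1] / "results" / "run"

if __name__ == "__main__":
    stage_degs(RUN)
    degsets = read_degsets(RUN / "degsets.json")
    sizes = {c: (len(s["up"]), len(s["down"])) for c, s in sorted(degsets.items())}
    print("up/down DEGs per condition:")
    print(json.dumps({c: list(v) for c, v in sizes.items()}, indent=0))
    genes = modeling_genes(degsets)
    print(f"{len(genes)} genes are DEGs in more than 5 conditions (GRN responses)")
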