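#!/usr/bin/env python
"""Generate the synthetic stress atlas that every later step analyses.

27 conditions (7 single stresses, 18 pairwise combinations, 2 control
batches) x 3 replicates; 2000 target genes, 50 TFs, sparse planted network,
additive combined-stress fold changes (b0 = -0.04, bx = 0.61, by = 0.69),
log2fc noise 0.5, replicate dispersion 0.25.  Writes the full input bundle
(expression, DE tables, annotations, orthology, reference network, truth)
to results/run/.
"""

import logging
from pathlib import Path

from stressatlas.pipeline import stage_simulate

logging.basicConfig(level=logging.INFO, format="%(message)s")
RUN = Path(__file__).resolve().parents[1] / "results" / "run"

if __name__ == "__main__":
    stage_simulate(RUN, seed=1, n_genes=2000, n_tfs=50)
    n_de = len(list((RUN / "de").glob("*.tsv")))
    print(f"bundle written to {RUN} ({n_de} DE contrast tables)")
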