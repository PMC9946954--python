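#!/usr/bin/env python
"""Cross-species checks: network vs reference, conserved DEG families.

Maps the inferred networks to orthogroup tuples and tests their overlap with
the planted-derived curated reference (1000 target shuffles); then tests
per-stress family-level DEG conservation against a second pseudo-species
whose DEG sets share families for cold/heat/salt but not darkness.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from stressatlas.compare import family_deg_ji, permute_reference, to_ortho_edges
from stressatlas.io import read_degsets, read_edge_list, read_family_map
from stressatlas.pipeline import stage_compare

RUN = Path(__file__).resolve().parents[1] / "results" / "run"

if __name__ == "__main__":
    stage_compare(RUN, n_perm=1000, seed=0)
    print("union network vs reference:", json.loads((RUN / "compare.json").read_text()))

    # high-confidence network: spurious-edge dilution removed
    hc = pd.read_csv(RUN / "hc_grn.tsv", sep="\t")
    fam_a = read_family_map(RUN / "families_a.tsv", strip_isoform_suffix=False)
    fam_b = read_family_map(RUN / "families_b.tsv", strip_isoform_suffix=False)
    ref = read_edge_list(RUN / "reference_edges.tsv", strip_isoform_suffix=False)
    obs, _ = to_ortho_edges(set(zip(hc["tf"], hc["target"])), fam_a)
    res = permute_reference(obs, ref, fam_b, n=1000, seed=0)
    print(f"high-confidence network vs reference: JI={res['ji']:.4f} p={res['p']:.4f}")

    # family-level conservation with a pseudo-species: conserved for C/H/S
    degsets = read_degsets(RUN / "degsets.json")
    rng = np.random.default_rng(0)
    b_gene = {fam: g for g, fam in fam_b.gene_to_family.items()}
    degs_a, degs_b = {}, {}
    for stress in ("C", "H", "S", "D"):
        degs_a[stress] = degsets[stress]["up"] | degsets[stress]["down"]
        fams = {fam_a.gene_to_family[g] for g in degs_a[stress] if g in fam_a.gene_to_family}
        if stress == "D":  # darkness: an unrelated response in the other species
            fams = set(rng.choice(sorted(set(fam_b.gene_to_family.values())), size=len(fams), replace=False))
        degs_b[stress] = {b_gene[f] for f in fams}
    table = family_deg_ji(degs_a, degs_b, fam_a, fam_b, n_perm=1000, seed=1)
    table.to_csv(RUN / "conserve.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
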