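"""Cross-species network and DEG-family comparisons.

Inferred regulator -> target edges are translated into orthogroup ->
orthogroup tuples through per-species gene-family maps, deduplicated, and
compared with a curated reference network by Jaccard index.  Significance
comes from shuffling the reference's regulator/target pairing (1000 times by
default) and recomputing the JI.  The same machinery tests whether two
species differentially express the same gene families per stress: family
sets holding at least one DEG are compared by JI against a null built by
shuffling each species' gene -> family assignment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import AnnotationMap, ReferenceNetwork


def to_ortho_edges(
    edges, family_map: AnnotationMap
) -> tuple[frozenset[tuple[str, str]], int]:
    """Map gene-level edges to orthogroup tuples; unmapped edges are dropped.

    Returns (tuple set, number of dropped edges).
    """
    fam = family_map.gene_to_family
    out = set()
    dropped = 0
    for r, t in edges:
        fr, ft = fam.get(r), fam.get(t)
        if fr is None or ft is None:
            dropped += 1
            continue
        out.add((fr, ft))
    return frozenset(out), dropped


def network_ji(a: frozenset, b: frozenset) -> float:
    """Jaccard index of two edge-tuple sets (0 when both are empty)."""
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def permute_reference(
    observed_ortho: frozenset,
    reference: ReferenceNetwork,
    reference_families: AnnotationMap | None = None,
    n: int = 1000,
    seed: int = 0,
    scheme: str = "targets",
) -> dict:
    """Empirical p-value for the observed network/reference JI.

    Each shuffle re-pairs the reference's regulators with targets — scheme
    "targets" permutes the target column holding regulators fixed (degree
    preserving on the regulator side); "rewire" permutes both columns
    independently.  p = (1 + #{JI_perm >= JI_obs}) / (n + 1).
    """
    if len(reference.regulators) < 2 or len(reference.targets) < 2:
        raise ValueError("reference needs at least 2 regulators and 2 targets")
    if scheme not in ("targets", "rewire"):
        raise ValueError(f"unknown shuffle scheme {scheme!r}")

    def _map(edge_iter) -> frozenset:
        if reference_families is None:
            return frozenset(edge_iter)
        return to_ortho_edges(edge_iter, reference_families)[0]

    ref_edges = sorted(reference.edges)
    regs = np.array([r for r, _ in ref_edges])
    tgts = np.array([t for _, t in ref_edges])
    ji_obs = network_ji(observed_ortho, _map(ref_edges))

    rng = np.random.default_rng(seed)
    null = np.empty(n)
    for i in range(n):
        perm_t = tgts[rng.permutation(len(tgts))]
        perm_r = regs[rng.permutation(len(regs))] if scheme == "rewire" else regs
        null[i] = network_ji(observed_ortho, _map(zip(perm_r, perm_t)))
    p = (1.0 + float((null >= ji_obs).sum())) / (n + 1.0)
    return {"ji": ji_obs, "p": p, "null": null}


def _family_set(genes, fam: dict[str, str], allowed: set[str]) -> set[str]:
    return {fam[g] for g in genes if g in fam and fam[g] in allowed}


def family_deg_ji(
    degs_a: dict[str, set[str]],
    degs_b: dict[str, set[str]],
    families_a: AnnotationMap,
    families_b: AnnotationMap,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-stress JI of differentially expressed gene families in two species.

    Only families present in both species' maps are used.  A family counts as
    differentially expressed when at least one member gene is a DEG (either
    direction).  The null shuffles each species' gene -> family assignment
    ``n_perm`` times.
    """
    fam_a, fam_b = families_a.gene_to_family, families_b.gene_to_family
    shared = set(fam_a.values()) & set(fam_b.values())
    if not shared:
        raise ValueError("the two species share no gene families")
    genes_a = sorted(g for g, f in fam_a.items() if f in shared)
    genes_b = sorted(g for g, f in fam_b.items() if f in shared)
    labels_a = np.array([fam_a[g] for g in genes_a])
    labels_b = np.array([fam_b[g] for g in genes_b])
    index_a = {g: i for i, g in enumerate(genes_a)}
    index_b = {g: i for i, g in enumerate(genes_b)}

    rng = np.random.default_rng(seed)
    rows = []
    for stress in sorted(set(degs_a) & set(degs_b)):
        idx_a = np.array([index_a[g] for g in degs_a[stress] if g in index_a], dtype=int)
        idx_b = np.array([index_b[g] for g in degs_b[stress] if g in index_b], dtype=int)
        obs = network_ji(
            frozenset(labels_a[idx_a]) if len(idx_a) else frozenset(),
            frozenset(labels_b[idx_b]) if len(idx_b) else frozenset(),
        )
        exceed = 0
        for _ in range(n_perm):
            pa = labels_a[rng.permutation(len(labels_a))[idx_a]] if len(idx_a) else []
            pb = labels_b[rng.permutation(len(labels_b))[idx_b]] if len(idx_b) else []
            ji = network_ji(frozenset(pa), frozenset(pb))
            if ji >= obs:
                exceed += 1
        rows.append(
            {"stress": stress, "ji": obs, "p": (1.0 + exceed) / (n_perm + 1.0)}
        )
    return pd.DataFrame(rows, columns=["stress", "ji", "p"])
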