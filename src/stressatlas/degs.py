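"""Differential-expression calling and dual-control consolidation.

A gene counts as differentially expressed in a condition only if it clears
the thresholds (BH-adjusted p < 0.05 and |log2fc| > 1, both strict) against
*both* control batches F and L.  The consolidated per-condition up/down sets
feed every downstream stage.
"""

from __future__ import annotations

from itertools import combinations

import pandas as pd

DEGSets = dict[str, dict[str, set[str]]]


def call_degs(
    table: pd.DataFrame, padj_max: float = 0.05, lfc_min: float = 1.0
) -> tuple[set[str], set[str]]:
    """Up/down gene sets from one DE contrast.

    Strict inequalities: a gene at padj == padj_max or |log2fc| == lfc_min is
    not called.
    """
    if padj_max <= 0 or lfc_min <= 0:
        raise ValueError("thresholds must be positive")
    sig = table[table["padj"] < padj_max]
    up = set(sig.loc[sig["log2fc"] > lfc_min, "gene"])
    down = set(sig.loc[sig["log2fc"] < -lfc_min, "gene"])
    return up, down


def consolidate_dual_control(
    vs_f: tuple[set[str], set[str]], vs_l: tuple[set[str], set[str]]
) -> tuple[set[str], set[str]]:
    """Keep only genes called in the same direction against both controls."""
    up_f, down_f = vs_f
    up_l, down_l = vs_l
    return up_f & up_l, down_f & down_l


def consolidate_de_tables(
    de_tables: dict[tuple[str, str], pd.DataFrame],
    conditions,
    padj_max: float = 0.05,
    lfc_min: float = 1.0,
) -> DEGSets:
    """Per-condition consolidated DEG sets from (condition, batch) DE tables."""
    degsets: DEGSets = {}
    for cond in conditions:
        calls = []
        for batch in ("F", "L"):
            if (cond, batch) not in de_tables:
                raise KeyError(f"missing DE table for condition {cond!r} vs control {batch}")
            calls.append(call_degs(de_tables[(cond, batch)], padj_max, lfc_min))
        up, down = consolidate_dual_control(*calls)
        degsets[cond] = {"up": up, "down": down}
    return degsets


def deg_frequency(degsets: DEGSets) -> dict[str, int]:
    """Number of conditions in which each gene is a DEG (either direction)."""
    counts: dict[str, int] = {}
    for sets in degsets.values():
        for g in sets["up"] | sets["down"]:
            counts[g] = counts.get(g, 0) + 1
    return counts


def modeling_genes(degsets: DEGSets, min_experiments: int = 5) -> set[str]:
    """Genes differentially expressed in *more than* ``min_experiments`` conditions."""
    return {g for g, n in deg_frequency(degsets).items() if n > min_experiments}


def upset_intersections(
    degsets: DEGSets, direction: str
) -> dict[frozenset[str], int]:
    """Exact-membership intersection counts over the per-condition sets.

    Each gene is assigned to the one subset of conditions it belongs to, so
    the counts partition the union of all sets (as in an UpSet plot).
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    membership: dict[str, set[str]] = {}
    for cond, sets in degsets.items():
        for g in sets[direction]:
            membership.setdefault(g, set()).add(cond)
    counts: dict[frozenset[str], int] = {}
    for conds in membership.values():
        key = frozenset(conds)
        counts[key] = counts.get(key, 0) + 1
    return counts


def upset_brute_force(sets: dict[str, set[str]]) -> dict[frozenset[str], int]:
    """Independent oracle: enumerate every non-empty condition subset."""
    out: dict[frozenset[str], int] = {}
    names = sorted(sets)
    for r in range(1, len(names) + 1):
        for subset in combinations(names, r):
            inside = set.intersection(*(sets[c] for c in subset))
            outside = set.union(set(), *(sets[c] for c in names if c not in subset))
            n = len(inside - outside)
            if n:
                out[frozenset(subset)] = n
    return out
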