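"""Permutation-based pathway (functional-bin) activity calls.

For one condition and direction, the observed number of DEGs in each bin is
compared with counts obtained by drawing equally many genes uniformly from
the annotated universe.  The empirical p-value is
``(1 + #{permuted count >= observed}) / (n_perm + 1)`` and is BH-corrected
across bins within the condition x direction; the classical hypergeometric
tail p is reported alongside for comparison.  Bins are classified per
condition as U (only up significant), D (only down), UD (both), N (neither),
and the condition x bin matrix is ordered by average-linkage hierarchical
clustering on Jaccard distances between binary significance profiles.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .io import AnnotationMap


def truncate_bin(code: str, level: int) -> str:
    return ".".join(code.split(".")[:level])


def bin_membership(
    annotation: AnnotationMap, universe, level: int = 2
) -> tuple[list[str], list[str], np.ndarray]:
    """(genes, bins, membership matrix) over the annotated universe."""
    genes = sorted(g for g in universe if g in annotation.gene_to_bins)
    bins = sorted(
        {truncate_bin(b, level) for g in genes for b in annotation.gene_to_bins[g]}
    )
    bin_index = {b: i for i, b in enumerate(bins)}
    mat = np.zeros((len(genes), len(bins)), dtype=np.int8)
    for i, g in enumerate(genes):
        for b in annotation.gene_to_bins[g]:
            mat[i, bin_index[truncate_bin(b, level)]] = 1
    return genes, bins, mat


def enrich_bins(
    deg_set: set,
    annotation: AnnotationMap,
    universe: set,
    n_perm: int = 1000,
    seed: int = 0,
    level: int = 2,
) -> pd.DataFrame:
    """Per-bin permutation enrichment of ``deg_set`` within ``universe``.

    Returns a DataFrame with columns bin, n_bin, observed, p_perm, p_hyper,
    padj (BH over bins on the permutation p).
    """
    if not deg_set <= universe:
        raise ValueError("deg_set must be a subset of the universe")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; empirical p floor is {1/(n_perm+1):.3g}")
    genes, bins, mat = bin_membership(annotation, universe, level)
    n_genes = len(genes)
    bin_sizes = mat.sum(axis=0)
    gene_index = {g: i for i, g in enumerate(genes)}
    hits = [gene_index[g] for g in deg_set if g in gene_index]
    k = len(hits)
    observed = (
        mat[hits].sum(axis=0) if k else np.zeros(len(bins), dtype=int)
    )

    if k == 0:
        p_perm = np.ones(len(bins))
    else:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(bins), dtype=np.int64)
        chunk = max(1, min(n_perm, 200))
        done = 0
        while done < n_perm:
            m = min(chunk, n_perm - done)
            # m independent draws of k genes without replacement
            idx = np.argsort(rng.random((m, n_genes)), axis=1)[:, :k]
            counts = mat[idx].sum(axis=1)  # (m, n_bins)
            exceed += (counts >= observed).sum(axis=0)
            done += m
        p_perm = (1.0 + exceed) / (n_perm + 1.0)

    p_hyper = stats.hypergeom.sf(observed - 1, n_genes, bin_sizes, k)
    padj = multipletests(p_perm, method="fdr_bh")[1] if len(bins) else np.array([])
    return pd.DataFrame(
        {
            "bin": bins,
            "n_bin": bin_sizes,
            "observed": observed,
            "p_perm": p_perm,
            "p_hyper": p_hyper,
            "padj": padj,
        }
    )


def classify_bins(
    up: pd.DataFrame, down: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Merge up/down enrichment into one U/UD/D/N class per bin."""
    merged = up[["bin", "padj"]].merge(
        down[["bin", "padj"]], on="bin", how="outer", suffixes=("_up", "_down")
    )
    merged[["padj_up", "padj_down"]] = merged[["padj_up", "padj_down"]].fillna(1.0)
    sig_up = merged["padj_up"] < alpha
    sig_down = merged["padj_down"] < alpha
    cls = np.where(
        sig_up & sig_down, "UD", np.where(sig_up, "U", np.where(sig_down, "D", "N"))
    )
    return pd.DataFrame(
        {
            "bin": merged["bin"],
            "class": cls,
            "padj_up": merged["padj_up"],
            "padj_down": merged["padj_down"],
        }
    )


def activity_matrix(classified: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Condition x bin matrix of U/UD/D/N classes (missing cells are N)."""
    conditions = sorted(classified)
    bins = sorted({b for df in classified.values() for b in df["bin"]})
    out = pd.DataFrame("N", index=conditions, columns=bins)
    for cond, df in classified.items():
        for b, c in zip(df["bin"], df["class"]):
            out.loc[cond, b] = c
    return out


def _binary_profiles(matrix: pd.DataFrame) -> np.ndarray:
    """Each row becomes [up-significant bits, down-significant bits]."""
    vals = matrix.to_numpy()
    up = np.isin(vals, ("U", "UD")).astype(float)
    down = np.isin(vals, ("D", "UD")).astype(float)
    return np.hstack([up, down])


def cluster_activity_matrix(matrix: pd.DataFrame):
    """Row and column leaf orders from average-linkage Jaccard clustering.

    Labels are lexically sorted before clustering so the leaf order is
    deterministic under input permutation.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns to cluster")
    matrix = matrix.sort_index(axis=0).sort_index(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-zero profile pairs
        row_d = pdist(_binary_profiles(matrix), metric="jaccard")
        col_d = pdist(_binary_profiles(matrix.T), metric="jaccard")
    row_link = linkage(np.nan_to_num(row_d), method="average")
    col_link = linkage(np.nan_to_num(col_d), method="average")
    row_order = [matrix.index[i] for i in leaves_list(row_link)]
    col_order = [matrix.columns[i] for i in leaves_list(col_link)]
    return row_order, col_order, row_link, col_link


def robust_bins(
    classified: dict[str, pd.DataFrame],
    group_conditions,
    min_ratio: float = 0.7,
) -> pd.DataFrame:
    """Bins significant in the same direction in >70% of a stress group.

    ``classified`` maps condition -> classify_bins output; only the listed
    group conditions are consulted.  Returns bin, direction, ratio rows for
    robust bins (ratio strictly greater than ``min_ratio``).
    """
    group = [c for c in group_conditions]
    n = len(group)
    counts: dict[tuple[str, str], int] = {}
    for cond in group:
        df = classified[cond]
        for b, c in zip(df["bin"], df["class"]):
            if c in ("U", "UD"):
                counts[(b, "up")] = counts.get((b, "up"), 0) + 1
            if c in ("D", "UD"):
                counts[(b, "down")] = counts.get((b, "down"), 0) + 1
    rows = [
        {"bin": b, "direction": d, "ratio": cnt / n}
        for (b, d), cnt in sorted(counts.items())
        if cnt / n > min_ratio
    ]
    return pd.DataFrame(rows, columns=["bin", "direction", "ratio"])
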