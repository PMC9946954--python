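"""TF -> TF regulatory network: robust TFs, edge expectations, cut-off sweep.

A TF responds robustly to a stress group (all conditions sharing a stress
letter) when it is a DEG with consistent direction in more than 70% of the
group's conditions.  Across groups a TF is 'up', 'down', or 'ambiguous'
(robust in both directions somewhere).  An inferred TF_A -> TF_B edge is
*expected* when the regulation sign is consistent with both TFs' expression
directions: an activator's source and target move together, a repressor's
move oppositely.  Edges involving an ambiguous status or mode are ambiguous
and sit outside the expected/unexpected ratio.  A global cut-off on the
edge weight (maximum absolute relative coefficient across datasets) is
chosen to maximize expected / (expected + unexpected) among surviving edges.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .degs import DEGSets
from .design import StressDesign
from .io import AnnotationMap


def robust_tfs(
    degsets: DEGSets,
    tf_genes: set[str],
    design: StressDesign,
    min_ratio: float = 0.7,
) -> pd.DataFrame:
    """Per (tf, stress group, direction) consistency ratios above threshold.

    ratio = (# group conditions where the TF is a DEG in that direction)
    / (# group conditions); kept if strictly greater than ``min_ratio``.
    """
    rows = []
    for stress in design.single_codes:
        group = design.stress_group(stress)
        n = len(group)
        for direction in ("up", "down"):
            counts: dict[str, int] = {}
            for cond in group:
                for g in degsets[cond][direction] & tf_genes:
                    counts[g] = counts.get(g, 0) + 1
            for tf, cnt in sorted(counts.items()):
                if cnt / n > min_ratio:
                    rows.append(
                        {"tf": tf, "stress": stress, "direction": direction, "ratio": cnt / n}
                    )
    return pd.DataFrame(rows, columns=["tf", "stress", "direction", "ratio"])


def tf_status(robust: pd.DataFrame) -> dict[str, str]:
    """Collapse per-group robustness to one status per TF.

    'up' or 'down' when every robust occurrence agrees; 'ambiguous' when a TF
    is robustly up in one group and down in another.
    """
    status: dict[str, str] = {}
    for tf, grp in robust.groupby("tf"):
        dirs = set(grp["direction"])
        status[tf] = dirs.pop() if len(dirs) == 1 else "ambiguous"
    return status


def classify_edge(source_status: str, source_mode: str, target_status: str) -> str:
    """expected / unexpected / ambiguous for one regulatory edge."""
    if "ambiguous" in (source_status, source_mode, target_status):
        return "ambiguous"
    if source_mode == "activator":
        return "expected" if source_status == target_status else "unexpected"
    if source_mode == "repressor":
        return "expected" if source_status != target_status else "unexpected"
    raise ValueError(f"unknown regulation mode {source_mode!r}")


def build_tfrn(
    union: pd.DataFrame,
    tf_genes: set[str],
    status: dict[str, str],
) -> pd.DataFrame:
    """TF -> TF edges from the union network.

    Weight = highest absolute relative coefficient across datasets for the
    ordered pair; mode from sign consistency of that pair's coefficients.
    TFs without a robust status are treated as ambiguous.
    """
    tf_edges = union[union["target"].isin(tf_genes)]
    rows = []
    for (src, tgt), grp in tf_edges.groupby(["tf", "target"]):
        coefs = grp["coef"]
        if (coefs > 0).all():
            mode = "activator"
        elif (coefs < 0).all():
            mode = "repressor"
        else:
            mode = "ambiguous"
        s_status = status.get(src, "ambiguous")
        t_status = status.get(tgt, "ambiguous")
        rows.append(
            {
                "source": src,
                "target": tgt,
                "coef": float(grp["rel_coef"].max()),
                "mode": mode,
                "source_status": s_status,
                "target_status": t_status,
                "expectation": classify_edge(s_status, mode, t_status),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "source", "target", "coef", "mode",
            "source_status", "target_status", "expectation",
        ],
    )


def optimize_cutoff(
    edges: pd.DataFrame, step: float = 0.01
) -> tuple[float, float, int, pd.DataFrame]:
    """Sweep an absolute-coefficient cut-off for the best expected-edge ratio.

    At each threshold t in [0, max|coef|] (step ``step``) the surviving edges
    are those with |coef| >= t; the ratio is expected / (expected +
    unexpected) among them (ambiguous edges never enter the ratio).  Returns
    (cutoff, ratio, number of TFs retaining at least one edge, sweep table);
    ties break toward the smallest threshold.
    """
    classifiable = edges[edges["expectation"] != "ambiguous"]
    if classifiable.empty:
        raise ValueError("all edges are ambiguous; the expected-edge ratio is undefined")
    weights = edges["coef"].abs().to_numpy()
    expected = (edges["expectation"] == "expected").to_numpy()
    unexpected = (edges["expectation"] == "unexpected").to_numpy()

    thresholds = np.round(np.arange(0.0, weights.max() + step, step), 10)
    rows = []
    for t in thresholds:
        alive = weights >= t
        n_exp = int((expected & alive).sum())
        n_unexp = int((unexpected & alive).sum())
        if n_exp + n_unexp == 0:
            continue
        ratio = n_exp / (n_exp + n_unexp)
        n_tfs = len(
            set(edges.loc[alive, "source"]) | set(edges.loc[alive, "target"])
        )
        rows.append(
            {"cutoff": float(t), "ratio": ratio, "n_edges": int(alive.sum()), "n_tfs": n_tfs}
        )
    sweep = pd.DataFrame(rows)
    best_row = sweep.loc[sweep["ratio"].idxmax()]
    # ties -> smallest threshold: idxmax returns the first maximum (ascending sweep)
    return (
        float(best_row["cutoff"]),
        float(best_row["ratio"]),
        int(best_row["n_tfs"]),
        sweep,
    )


def tf_modes(hc_grn: pd.DataFrame) -> dict[str, str]:
    """A TF's prevailing regulation mode across its high-confidence targets.

    Majority vote over activator/repressor edge modes; ambiguous on a tie or
    when no un-ambiguous edge exists.
    """
    modes: dict[str, str] = {}
    for tf, grp in hc_grn.groupby("tf"):
        n_act = int((grp["mode"] == "activator").sum())
        n_rep = int((grp["mode"] == "repressor").sum())
        if n_act > n_rep:
            modes[tf] = "activator"
        elif n_rep > n_act:
            modes[tf] = "repressor"
        else:
            modes[tf] = "ambiguous"
    return modes


def bin_status(robust_bin_table: pd.DataFrame) -> dict[str, str]:
    """Collapse robust-bin rows (possibly from several groups) to one status."""
    status: dict[str, str] = {}
    for b, grp in robust_bin_table.groupby("bin"):
        dirs = set(grp["direction"])
        status[b] = dirs.pop() if len(dirs) == 1 else "ambiguous"
    return status


def tf_bin_links(
    hc_grn: pd.DataFrame,
    annotation: AnnotationMap,
    robust_bin_table: pd.DataFrame,
    robust_tf_table: pd.DataFrame,
    universe: set[str],
    min_fraction: float = 0.05,
    level: int = 2,
) -> pd.DataFrame:
    """TF -> functional-bin edges where a TF controls >= 5% of a bin's genes.

    fraction = (# bin genes in the universe whose high-confidence regulator
    is the TF) / (# bin genes in the universe).  Each kept edge is classified
    as expected/unexpected/ambiguous from the TF's robust direction, the
    TF's prevailing mode, and the bin's robust direction.
    """
    from .pathways import truncate_bin

    regulator_of = dict(zip(hc_grn["target"], hc_grn["tf"]))
    modes = tf_modes(hc_grn)
    t_status = tf_status(robust_tf_table)
    b_status = bin_status(robust_bin_table)

    bin_genes: dict[str, set[str]] = {}
    for g in universe:
        for b in annotation.gene_to_bins.get(g, ()):  # noqa: B909
            bin_genes.setdefault(truncate_bin(b, level), set()).add(g)

    rows = []
    for b in sorted(b_status):
        genes = bin_genes.get(b, set())
        if not genes:
            continue  # empty bin in this universe
        counts: dict[str, int] = {}
        for g in genes:
            tf = regulator_of.get(g)
            if tf is not None:
                counts[tf] = counts.get(tf, 0) + 1
        for tf in sorted(t_status):
            frac = counts.get(tf, 0) / len(genes)
            if frac >= min_fraction and counts.get(tf, 0) > 0:
                rows.append(
                    {
                        "tf": tf,
                        "bin": b,
                        "fraction": frac,
                        "tf_status": t_status[tf],
                        "tf_mode": modes.get(tf, "ambiguous"),
                        "bin_status": b_status[b],
                        "expectation": classify_edge(
                            t_status[tf], modes.get(tf, "ambiguous"), b_status[b]
                        ),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["tf", "bin", "fraction", "tf_status", "tf_mode", "bin_status", "expectation"],
    )
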