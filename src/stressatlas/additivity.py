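"""The additive linear model of combined-stress gene expression.

For a gene g and a stress pair, let Sx and Sy be the log2 fold changes under
the two single stresses and Sxy under the combination.  The model is

    Sxy = b0 + bx * Sx + by * Sy

fitted by ordinary least squares, either on the 9-category cell means
(genes grouped by their down / no-change / up status in Sx and Sy, means of
Sx, Sy, Sxy per cell, pooled over focal stresses) or on raw per-gene values
pooled over all combinations of one focal stress.  The per-stress Sx
coefficient quantifies how strongly that stress imposes its own response on
combinations — its dominance.

Two orientations are supported when assembling (gene, combination) rows:
``focal`` (each combination contributes to both of its stresses' groups,
with Sx the focal stress) and ``first-letter`` (each combination contributes
once, Sx being the first letter of its code — the orientation in which the
synthetic generator defines its coefficients).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .degs import DEGSets
from .design import StressDesign


@dataclass(frozen=True)
class AdditivityFit:
    b0: float
    bx: float
    by: float
    r2: float
    mae: float
    rmse: float
    n: int
    scope: str


class CollinearityError(ValueError):
    pass


def categorize(gene: str, x: str, y: str, degsets: DEGSets) -> tuple[str, str]:
    """(Sx status, Sy status) from the single-stress consolidated DEG calls."""

    def status(stress: str) -> str:
        if gene in degsets[stress]["up"]:
            return "up"
        if gene in degsets[stress]["down"]:
            return "down"
        return "nc"

    return status(x), status(y)


def assemble(
    lfc: pd.DataFrame,
    degsets: DEGSets,
    design: StressDesign,
    orientation: str = "focal",
) -> pd.DataFrame:
    """Long table of (focal, combo, gene, sx, sy, sxy, sx_status, sy_status).

    ``lfc`` is a genes x conditions frame of log2 fold changes.  Genes absent
    from a condition's column (NaN) are dropped from that combination.
    """
    if orientation not in ("focal", "first-letter"):
        raise ValueError(f"unknown orientation {orientation!r}")
    frames = []
    for code in design.combined_codes:
        a, b = code[0], code[1]
        pairs = [(a, b), (b, a)] if orientation == "focal" else [(a, b)]
        sub = lfc[[a, b, code]].dropna()
        for x, y in pairs:
            status = np.array([categorize(g, x, y, degsets) for g in sub.index])
            frames.append(
                pd.DataFrame(
                    {
                        "focal": x,
                        "combo": code,
                        "gene": sub.index,
                        "sx": sub[x].to_numpy(),
                        "sy": sub[y].to_numpy(),
                        "sxy": sub[code].to_numpy(),
                        "sx_status": status[:, 0] if len(status) else [],
                        "sy_status": status[:, 1] if len(status) else [],
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def average_cells(long: pd.DataFrame) -> pd.DataFrame:
    """Mean Sx, Sy, Sxy per (focal stress, Sx status, Sy status) cell.

    All 9 status combinations are reported per focal stress; empty cells get
    count 0 and NaN means (they are excluded from the global regression).
    """
    stats = (
        long.groupby(["focal", "sx_status", "sy_status"])
        .agg(sx=("sx", "mean"), sy=("sy", "mean"), sxy=("sxy", "mean"), count=("gene", "size"))
        .reset_index()
    )
    full = pd.MultiIndex.from_product(
        [sorted(long["focal"].unique()), ["down", "nc", "up"], ["down", "nc", "up"]],
        names=["focal", "sx_status", "sy_status"],
    ).to_frame(index=False)
    cells = full.merge(stats, on=["focal", "sx_status", "sy_status"], how="left")
    cells["count"] = cells["count"].fillna(0).astype(int)
    return cells


def _ols(sx: np.ndarray, sy: np.ndarray, sxy: np.ndarray, scope: str) -> AdditivityFit:
    design = np.column_stack([np.ones_like(sx), sx, sy])
    if len(sxy) < 3 or np.linalg.matrix_rank(design) < 3:
        cond = np.linalg.cond(design) if len(sxy) else np.inf
        raise CollinearityError(
            f"predictors are collinear or too few points (condition number {cond:.3g})"
        )
    coef, _res, _rank, _sv = np.linalg.lstsq(design, sxy, rcond=None)
    fitted = design @ coef
    resid = sxy - fitted
    ss_tot = float(np.sum((sxy - sxy.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0
    return AdditivityFit(
        b0=float(coef[0]),
        bx=float(coef[1]),
        by=float(coef[2]),
        r2=r2,
        mae=float(np.abs(resid).mean()),
        rmse=float(np.sqrt((resid**2).mean())),
        n=len(sxy),
        scope=scope,
    )


def fit_global(cells: pd.DataFrame) -> AdditivityFit:
    """OLS of mean Sxy on mean Sx and Sy over all non-empty cells, unweighted."""
    filled = cells[cells["count"] > 0]
    return _ols(
        filled["sx"].to_numpy(),
        filled["sy"].to_numpy(),
        filled["sxy"].to_numpy(),
        scope="global-averaged",
    )


def fit_per_stress(long: pd.DataFrame, focal: str) -> AdditivityFit:
    """OLS on raw per-gene values pooled over one focal stress's combinations."""
    sub = long[long["focal"] == focal]
    if sub.empty:
        raise ValueError(f"no rows for focal stress {focal!r}")
    return _ols(
        sub["sx"].to_numpy(), sub["sy"].to_numpy(), sub["sxy"].to_numpy(),
        scope="per-stress",
    )


def fit_all_stresses(long: pd.DataFrame) -> dict[str, AdditivityFit]:
    return {f: fit_per_stress(long, f) for f in sorted(long["focal"].unique())}


def dominance_ranking(fits: dict[str, AdditivityFit]) -> tuple[list[str], bool]:
    """Stresses sorted by descending Sx coefficient; ties break alphabetically.

    Returns (ranking, had_ties).
    """
    items = sorted(fits.items(), key=lambda kv: (-kv[1].bx, kv[0]))
    bxs = [f.bx for _s, f in items]
    had_ties = len(set(bxs)) < len(bxs)
    return [s for s, _f in items], had_ties


def classify_outcome(sx: float, sy: float, sxy: float) -> str:
    """'higher' / 'lower' / 'within' the range of the two single responses."""
    if sxy > max(sx, sy):
        return "higher"
    if sxy < min(sx, sy):
        return "lower"
    return "within"


def classify_outcomes(long: pd.DataFrame) -> pd.Series:
    hi = np.maximum(long["sx"], long["sy"])
    lo = np.minimum(long["sx"], long["sy"])
    return pd.Series(
        np.where(long["sxy"] > hi, "higher", np.where(long["sxy"] < lo, "lower", "within")),
        index=long.index,
        name="outcome",
    )


def condition_log2fc(
    de_tables: dict[tuple[str, str], pd.DataFrame], conditions
) -> pd.DataFrame:
    """Per-condition log2fc: the mean of the vs-F and vs-L contrast estimates.

    Genes missing from either contrast get NaN for that condition.
    """
    cols = {}
    for cond in conditions:
        f = de_tables[(cond, "F")].set_index("gene")["log2fc"]
        l = de_tables[(cond, "L")].set_index("gene")["log2fc"]
        cols[cond] = (f + l) / 2.0
    return pd.DataFrame(cols)
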