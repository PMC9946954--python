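"""Gene-regulatory-network inference via penalized linear regression.

One model per differentially expressed gene (response) per dataset: the
predictors are the differentially expressed transcription factors, the data
are log2(TPM+1) expression values standardized per gene within the dataset
slice.  Eight slices are fitted — seven stress-specific ones (all conditions
containing the stress letter, no controls) and ALL (every sample).

The model is ElasticNet: squared loss / 2n plus
``strength * (mix * |b|_1 + (1 - mix) / 2 * |b|_2^2)``.  Hyperparameters are
chosen on a grid (mix 0.1..0.9 step 0.1; strength 0, 0.001, 0.01, 0.05, 0.1,
0.5, 1, 1.5, 2, 10, 100) by minimizing mean cross-validated MSE with seeded
contiguous-block folds; strength 0 falls back to (minimum-norm) ordinary
least squares.  The chosen model is refit on the full slice and its
in-sample R2 is the quality filter (R2 > 0.8 by default).  The union of the
seven stress-specific networks is reduced to a high-confidence GRN by
keeping, per target, the single TF with the highest absolute relative
coefficient across datasets; sign consistency across the supporting
datasets classifies the TF as activator, repressor, or ambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, enet_path

from .degs import DEGSets, modeling_genes
from .design import StressDesign
from .io import ExpressionMatrix

MIX_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1))
STRENGTH_GRID: tuple[float, ...] = (0.0, 0.001, 0.01, 0.05, 0.1, 0.5, 1.0, 1.5, 2.0, 10.0, 100.0)
ALL_DATASET = "ALL"


@dataclass
class RegressionModel:
    """One fitted penalized model for a single response gene."""

    target: str
    dataset: str
    intercept: float
    coefficients: dict[str, float]
    mix: float
    strength: float
    r2: float
    n: int
    cv_mse: float

    def relative_coefficients(self) -> dict[str, float]:
        """|coef| divided by the sum of |coef| within this model."""
        total = sum(abs(c) for c in self.coefficients.values())
        if total == 0:
            return {tf: 0.0 for tf in self.coefficients}
        return {tf: abs(c) / total for tf, c in self.coefficients.items()}

    def nonzero(self) -> dict[str, float]:
        return {tf: c for tf, c in self.coefficients.items() if c != 0.0}


@dataclass
class DatasetSlice:
    """Standardized response/predictor matrices for one dataset."""

    dataset: str
    samples: list[str]
    responses: pd.DataFrame  # samples x response genes (standardized)
    predictors: pd.DataFrame  # samples x TFs (standardized)
    cv_folds: int
    dropped_constant: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.samples)


def _standardize(log_values: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    mean = log_values.mean(axis=0)
    sd = log_values.std(axis=0, ddof=0)
    ok = sd > 1e-12
    z = (log_values - mean) / sd.where(ok, 1.0)
    return z, ok


def prepare_slices(
    expr: ExpressionMatrix,
    degsets: DEGSets,
    tf_genes: set[str],
    design: StressDesign,
    min_experiments: int = 5,
    stress_cv_folds: int = 3,
    all_cv_folds: int = 5,
) -> dict[str, DatasetSlice]:
    """Build the 7 stress-specific slices plus ALL.

    Responses are DEGs seen in more than ``min_experiments`` conditions;
    predictors are the TFs among those responses.  Values are log2(TPM+1),
    z-scored per gene within each slice; genes constant within a slice are
    dropped from it (recorded on the slice).
    """
    responses = sorted(modeling_genes(degsets, min_experiments) & set(expr.genes))
    tfs = sorted(set(responses) & tf_genes)
    if not responses:
        raise ValueError("no modeling genes: nothing is a DEG in enough conditions")
    if not tfs:
        raise ValueError("no differentially expressed TFs among the modeling genes")

    log_all = np.log2(expr.values.loc[responses].T + 1.0)  # samples x genes

    slices: dict[str, DatasetSlice] = {}
    specs = [(s, list(design.stress_group(s)), stress_cv_folds) for s in design.single_codes]
    specs.append((ALL_DATASET, list(design.conditions), all_cv_folds))
    for name, conditions, folds in specs:
        samples = expr.samples_for(conditions)
        if len(samples) < 2 * folds:
            raise ValueError(
                f"dataset {name!r} has {len(samples)} samples; need >= {2 * folds} "
                f"for {folds}-fold cross-validation"
            )
        z, ok = _standardize(log_all.loc[samples])
        keep = [g for g in responses if ok[g]]
        slices[name] = DatasetSlice(
            dataset=name,
            samples=samples,
            responses=z[keep],
            predictors=z[[t for t in tfs if ok[t]]],
            cv_folds=folds,
            dropped_constant=[g for g in responses if not ok[g]],
        )
    return slices


def _fold_blocks(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Contiguous blocks of a seeded shuffle of the sample indices."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [np.asarray(b) for b in np.array_split(order, folds)]


def _ols(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, _res, rank, _sv = np.linalg.lstsq(x, y, rcond=None)
    return coef  # minimum-norm solution when rank-deficient


def fit_elasticnet(
    y: np.ndarray,
    x: np.ndarray,
    cv_folds: int,
    mix_grid: tuple[float, ...] = MIX_GRID,
    strength_grid: tuple[float, ...] = STRENGTH_GRID,
    seed: int = 0,
    target: str = "",
    dataset: str = "",
    predictor_names: list[str] | None = None,
) -> RegressionModel:
    """Grid-search ElasticNet for one response, refit on the full slice.

    The cross-validated MSE surface is computed with warm-started coordinate
    descent along the strength path for each mix value; strength 0 is an OLS
    fit.  Ties in CV error break toward the smaller strength, then smaller
    mix.  The returned R2 is in-sample after the refit.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n, m = x.shape
    if n < cv_folds:
        raise ValueError(f"n={n} is smaller than cv_folds={cv_folds}")
    if predictor_names is None:
        predictor_names = [f"x{j}" for j in range(m)]

    pos_strengths = sorted((s for s in strength_grid if s > 0), reverse=True)
    has_zero = any(s == 0 for s in strength_grid)
    blocks = _fold_blocks(n, cv_folds, seed)

    # squared-error accumulators: [mix, strength] including the zero column
    strengths_sorted = ([0.0] if has_zero else []) + sorted(s for s in strength_grid if s > 0)
    s_index = {s: i for i, s in enumerate(strengths_sorted)}
    sse = np.zeros((len(mix_grid), len(strengths_sorted)))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for test_idx in blocks:
            mask = np.ones(n, dtype=bool)
            mask[test_idx] = False
            x_tr, y_tr = x[mask], y[mask]
            x_te, y_te = x[test_idx], y[test_idx]
            xm, ym = x_tr.mean(axis=0), y_tr.mean()
            x_trc, y_trc = x_tr - xm, y_tr - ym
            x_tec = x_te - xm
            if has_zero:
                coef0 = _ols(x_trc, y_trc)
                resid = y_te - (ym + x_tec @ coef0)
                sse[:, s_index[0.0]] += resid @ resid
            for mi, mix in enumerate(mix_grid):
                _alphas, coefs, _gaps = enet_path(
                    x_trc, y_trc, l1_ratio=mix, alphas=pos_strengths
                )
                preds = ym + x_tec @ coefs  # (n_test, n_alphas)
                resid = y_te[:, None] - preds
                for ai, s in enumerate(pos_strengths):
                    sse[mi, s_index[s]] += resid[:, ai] @ resid[:, ai]

        # pick: min mean CV MSE, ties -> smaller strength, then smaller mix
        cv_mse = sse / n
        best = (np.inf, np.inf, np.inf)
        for si, s in enumerate(strengths_sorted):
            for mi, mix in enumerate(mix_grid):
                key = (cv_mse[mi, si], s, mix)
                if key < best:
                    best = key
        best_mse, best_strength, best_mix = best

        # refit on the full slice
        if best_strength == 0.0:
            xm, ym = x.mean(axis=0), y.mean()
            coef = _ols(x - xm, y - ym)
            intercept = float(ym - xm @ coef)
        else:
            model = ElasticNet(alpha=best_strength, l1_ratio=best_mix, fit_intercept=True)
            model.fit(x, y)
            coef = model.coef_
            intercept = float(model.intercept_)

    fitted = intercept + x @ coef
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return RegressionModel(
        target=target,
        dataset=dataset,
        intercept=intercept,
        coefficients=dict(zip(predictor_names, (float(c) for c in coef))),
        mix=float(best_mix),
        strength=float(best_strength),
        r2=r2,
        n=n,
        cv_mse=float(best_mse),
    )


def fit_slice(dslice: DatasetSlice, seed: int = 0, targets=None) -> list[RegressionModel]:
    """Fit one model per response gene in a slice (TF self-prediction excluded)."""
    models = []
    tf_names = list(dslice.predictors.columns)
    x_full = dslice.predictors.to_numpy()
    wanted = list(dslice.responses.columns) if targets is None else [
        t for t in targets if t in dslice.responses.columns
    ]
    for gene in wanted:
        y = dslice.responses[gene].to_numpy()
        if gene in dslice.predictors.columns:
            keep = [j for j, t in enumerate(tf_names) if t != gene]
            x = x_full[:, keep]
            names = [tf_names[j] for j in keep]
        else:
            x, names = x_full, tf_names
        models.append(
            fit_elasticnet(
                y,
                x,
                dslice.cv_folds,
                seed=seed,
                target=gene,
                dataset=dslice.dataset,
                predictor_names=names,
            )
        )
    return models


def models_to_frame(models: list[RegressionModel]) -> pd.DataFrame:
    """Long edge table: one row per nonzero coefficient, with model metadata."""
    rows = []
    for m in models:
        rel = m.relative_coefficients()
        for tf, coef in m.nonzero().items():
            rows.append(
                {
                    "dataset": m.dataset,
                    "tf": tf,
                    "target": m.target,
                    "coef": coef,
                    "rel_coef": rel[tf],
                    "r2": m.r2,
                }
            )
    return pd.DataFrame(rows, columns=["dataset", "tf", "target", "coef", "rel_coef", "r2"])


def build_networks(
    models: list[RegressionModel],
    r2_min: float = 0.8,
    union_datasets=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter models by R2 (strict >) and take the stress-specific union.

    Returns (all kept edges, union edges).  The ALL dataset is kept in the
    first frame for comparison but excluded from the union by default.
    """
    kept = [m for m in models if m.r2 > r2_min]
    edges = models_to_frame(kept)
    if union_datasets is None:
        union = edges[edges["dataset"] != ALL_DATASET]
    else:
        union = edges[edges["dataset"].isin(set(union_datasets))]
    return edges, union.reset_index(drop=True)


def select_high_confidence(union: pd.DataFrame) -> pd.DataFrame:
    """One TF per target: the highest absolute relative coefficient.

    Across datasets the maximum relative coefficient per (tf, target) pair is
    taken first; per target the argmax TF wins (lexicographically smallest TF
    on ties).  The regulation mode is activator if every supporting dataset's
    coefficient is positive, repressor if all negative, else ambiguous.
    """
    if union.empty:
        raise ValueError("union network is empty")
    best_rel = (
        union.groupby(["target", "tf"], as_index=False)
        .agg(rel_coef=("rel_coef", "max"), n_datasets=("dataset", "nunique"))
    )
    rows = []
    for target, grp in best_rel.groupby("target"):
        grp = grp.sort_values(["rel_coef", "tf"], ascending=[False, True])
        top = grp.iloc[0]
        coefs = union.loc[
            (union["target"] == target) & (union["tf"] == top["tf"]), "coef"
        ]
        if (coefs > 0).all():
            mode = "activator"
        elif (coefs < 0).all():
            mode = "repressor"
        else:
            mode = "ambiguous"
        rows.append(
            {
                "target": target,
                "tf": top["tf"],
                "rel_coef": float(top["rel_coef"]),
                "n_datasets": int(top["n_datasets"]),
                "mode": mode,
            }
        )
    return pd.DataFrame(rows).sort_values("target").reset_index(drop=True)


def model_quality_curve(
    models: list[RegressionModel], thresholds=None
) -> pd.DataFrame:
    """Counts of responses with R2 >= threshold, per dataset."""
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 1.0001, 0.05), 2)
    datasets = sorted({m.dataset for m in models})
    rows = []
    for t in thresholds:
        row = {"threshold": float(t)}
        for d in datasets:
            row[d] = sum(1 for m in models if m.dataset == d and m.r2 >= t)
        rows.append(row)
    return pd.DataFrame(rows)
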