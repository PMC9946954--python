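"""Validation experiments: oracle comparisons, parameter recovery, calibration.

Every function here builds its own synthetic inputs, runs the corresponding
pipeline operation, and returns summary numbers.  They are deliberately
self-contained so the same computation backs the test suite, the acceptance
report, and the analysis drivers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import set_metrics
from .additivity import assemble, average_cells, fit_global
from .compare import family_deg_ji
from .design import make_design
from .grn import fit_elasticnet
from .io import AnnotationMap
from .pathways import enrich_bins
from .synthetic import plant_truth, simulate_log2fc, uniform_additivity
from .tfrn import optimize_cutoff


# ---------------------------------------------------------------------------
# set metrics vs brute-force oracle


def metric_oracle_deviation(n_triples: int = 1000, seed: int = 0) -> dict:
    """Compare the three set metrics with naive element-wise counting.

    Random set triples (including empty sets); returns the maximum absolute
    deviation and whether every value stayed in its documented range.
    """
    rng = np.random.default_rng(seed)
    pool = [f"g{i}" for i in range(40)]

    def draw():
        k = int(rng.integers(0, 21))
        return set(rng.choice(pool, size=k, replace=False)) if k else set()

    max_dev = 0.0
    in_range = True
    for _ in range(n_triples):
        sx, sy, sxy = draw(), draw(), draw()
        sim = set_metrics.similarity(sx, sy)
        sup = set_metrics.suppression(sx, sy, sxy)
        nov = set_metrics.novelty(sx, sy, sxy)
        union = len({*sx, *sy})
        b_sim = (sum(1 for g in sx if g in sy) / union) if union else 0.0
        b_sup = (sum(1 for g in sx if g not in sxy) / len(sx) if sx else 0.0) - (
            sum(1 for g in sy if g not in sxy) / len(sy) if sy else 0.0
        )
        b_nov = (
            sum(1 for g in sxy if g not in sx and g not in sy) / len(sxy) if sxy else 0.0
        )
        max_dev = max(max_dev, abs(sim - b_sim), abs(sup - b_sup), abs(nov - b_nov))
        in_range &= 0 <= sim <= 1 and -1 <= sup <= 1 and 0 <= nov <= 1
    # stated extremes must be exact
    exact = (
        set_metrics.suppression({"a"}, {"b"}, {"b"}) == 1.0
        and set_metrics.suppression({"b"}, {"a"}, {"b"}) == -1.0
        and set_metrics.suppression({"a"}, {"b"}, {"a", "b"}) == 0.0
    )
    return {"max_abs_deviation": max_dev, "all_in_range": in_range, "extremes_exact": exact}


# ---------------------------------------------------------------------------
# ElasticNet recovery on planted sparse linear data


def _planted_design(rng, n: int, n_tfs: int, k_active: int = 3):
    x = rng.normal(size=(n, n_tfs))
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    support = rng.choice(n_tfs, size=k_active, replace=False)
    beta = np.zeros(n_tfs)
    mags = rng.uniform(0.5, 1.5, size=k_active)
    mags[0] = 2.0  # a clear strongest regulator
    signs = np.where(rng.random(k_active) < 0.5, -1.0, 1.0)
    beta[support] = mags * signs
    return x, beta, int(support[0])


def grn_noiseless_recovery(
    n_targets: int = 500, n_tfs: int = 50, n: int = 100, seed: int = 0
) -> dict:
    """Zero-noise planted regressions: R2 and argmax-regulator agreement.

    The independent oracle is plain least squares (`numpy.linalg.lstsq`): on
    noiseless full-rank data its argmax coefficient is the planted strongest
    regulator, and the grid-searched model must agree for every target.
    """
    rng = np.random.default_rng(seed)
    n_exact = 0
    n_argmax = 0
    for _ in range(n_targets):
        x, beta, _strongest = _planted_design(rng, n, n_tfs)
        y = x @ beta
        model = fit_elasticnet(y, x, cv_folds=5, seed=0)
        coefs = np.array(list(model.coefficients.values()))
        n_exact += model.r2 > 0.999
        oracle = np.linalg.lstsq(
            np.column_stack([np.ones(n), x]), y, rcond=None
        )[0][1:]
        n_argmax += int(np.argmax(np.abs(coefs))) == int(np.argmax(np.abs(oracle)))
    return {
        "n_targets": n_targets,
        "frac_r2_exact": n_exact / n_targets,
        "argmax_agreement": n_argmax / n_targets,
    }


def grn_noisy_recovery(
    n_seeds: int = 20,
    targets_per_seed: int = 25,
    n_tfs: int = 50,
    n: int = 100,
    snr: float = 5.0,
    seed: int = 0,
) -> dict:
    """Top-regulator recovery at finite signal-to-noise ratio.

    Per target: 3 active of ``n_tfs`` predictors, noise scaled so that
    var(signal)/var(noise) = ``snr``; recovery means the fitted model's
    largest-|coefficient| TF is the planted strongest regulator.
    """
    recovered = 0
    total = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + 1000 + s)
        for _ in range(targets_per_seed):
            x, beta, strongest = _planted_design(rng, n, n_tfs)
            signal = x @ beta
            y = signal + rng.normal(0, float(np.std(signal)) / np.sqrt(snr), n)
            model = fit_elasticnet(y, x, cv_folds=5, seed=0)
            coefs = np.abs(np.array(list(model.coefficients.values())))
            recovered += int(np.argmax(coefs)) == strongest
            total += 1
    return {"n_targets": total, "top_regulator_recovery": recovered / total}


# ---------------------------------------------------------------------------
# cut-off sweep vs exhaustive enumeration


def cutoff_sweep_check(
    n_networks: int = 5, n_edges: int = 200, seed: int = 0
) -> dict:
    """Compare the 0.01-step sweep with exhaustive threshold enumeration.

    Edge weights are drawn on the 0.01 grid (the resolution at which relative
    coefficients are swept), so enumerating every distinct weight is an exact
    oracle for the sweep.
    """
    rng = np.random.default_rng(seed)
    max_ratio_gap = 0.0
    argmax_ok = True
    for _ in range(n_networks):
        rows = [
            {
                "source": f"s{rng.integers(12)}",
                "target": f"t{rng.integers(40)}",
                "coef": round(float(rng.random()), 2),
                "expectation": str(
                    rng.choice(["expected", "unexpected", "ambiguous"], p=[0.4, 0.4, 0.2])
                ),
            }
            for _ in range(n_edges)
        ]
        edges = pd.DataFrame(rows)
        cutoff, ratio, _n_tfs, sweep = optimize_cutoff(edges, step=0.01)
        best = 0.0
        for t in sorted({0.0, *(abs(r["coef"]) for r in rows)}):
            ne = sum(
                1 for r in rows if abs(r["coef"]) >= t and r["expectation"] == "expected"
            )
            nu = sum(
                1 for r in rows if abs(r["coef"]) >= t and r["expectation"] == "unexpected"
            )
            if ne + nu:
                best = max(best, ne / (ne + nu))
        max_ratio_gap = max(max_ratio_gap, abs(best - ratio))
        argmax_ok &= ratio == sweep["ratio"].max()
    return {"max_ratio_gap": max_ratio_gap, "argmax_is_global": argmax_ok}


# ---------------------------------------------------------------------------
# additivity parameter recovery


def additivity_recovery(
    n_seeds: int = 50,
    n_genes: int = 2000,
    noise_sd: float = 0.5,
    params: tuple[float, float, float] = (-0.04, 0.61, 0.69),
    seed: int = 0,
) -> dict:
    """Recover the planted additive coefficients from noisy simulated atlases.

    Per seed: plant the coefficients, simulate log2 fold changes, run the
    9-category averaging and the global OLS in the generative (first-letter)
    orientation, and record the estimates.
    """
    design = make_design()
    b0, bx, by = params
    ests = []
    r2s = []
    for s in range(n_seeds):
        truth = plant_truth(
            design,
            n_genes=n_genes,
            n_tfs=50,
            noise_sd=noise_sd,
            seed=seed + 10_000 + s,
            additivity_params=uniform_additivity(design, b0, bx, by),
        )
        lfc = simulate_log2fc(truth, design)
        genes = truth.all_genes
        frame = pd.DataFrame({c: lfc[c] for c in design.stress_conditions}, index=list(genes))
        degsets = {
            c: {
                "up": {g for g, v in zip(genes, lfc[c]) if v > 1},
                "down": {g for g, v in zip(genes, lfc[c]) if v < -1},
            }
            for c in design.stress_conditions
        }
        long = assemble(frame, degsets, design, orientation="first-letter")
        fit = fit_global(average_cells(long))
        ests.append((fit.b0, fit.bx, fit.by))
        r2s.append(fit.r2)
    est = np.array(ests)
    return {
        "b0_mean": float(est[:, 0].mean()),
        "bx_mean": float(est[:, 1].mean()),
        "by_mean": float(est[:, 2].mean()),
        "max_abs_error": float(
            np.max(np.abs(est - np.array(params)[None, :]))
        ),
        "r2_mean": float(np.mean(r2s)),
        "r2_min": float(np.min(r2s)),
        "n_seeds": n_seeds,
    }


def additivity_scaling(
    ns: tuple[int, ...] = (200, 2000, 20000),
    n_seeds: int = 50,
    noise_sd: float = 0.5,
    params: tuple[float, float, float] = (-0.04, 0.61, 0.69),
    seed: int = 0,
) -> dict:
    """Bias and RMSE of the per-gene OLS estimator across sample sizes.

    Fits the raw per-gene regression (one focal stress, first-letter
    orientation pooled over all combinations) so n scales with gene count;
    reports the fitted slope of log RMSE vs log n (expect about -1/2).
    """
    design = make_design()
    b0, bx, by = params
    bias = {}
    rmse = {}
    for n_genes in ns:
        errs = []
        for s in range(n_seeds):
            truth = plant_truth(
                design,
                n_genes=n_genes,
                n_tfs=50,
                noise_sd=noise_sd,
                seed=seed + 20_000 + s,
                additivity_params=uniform_additivity(design, b0, bx, by),
            )
            lfc = simulate_log2fc(truth, design)
            # direct per-gene OLS over every combination, generative orientation
            sx = np.concatenate([lfc[c[0]] for c in design.combined_codes])
            sy = np.concatenate([lfc[c[1]] for c in design.combined_codes])
            sxy = np.concatenate([lfc[c] for c in design.combined_codes])
            coef, *_ = np.linalg.lstsq(
                np.column_stack([np.ones_like(sx), sx, sy]), sxy, rcond=None
            )
            errs.append(coef[1] - bx)
        errs = np.array(errs)
        bias[n_genes] = float(errs.mean())
        rmse[n_genes] = float(np.sqrt((errs**2).mean()))
    logs_n = np.log(np.array(list(rmse.keys()), dtype=float))
    logs_r = np.log(np.array(list(rmse.values())))
    slope = float(np.polyfit(logs_n, logs_r, 1)[0])
    return {"bias": bias, "rmse": rmse, "rmse_log_slope": slope, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# permutation-test calibration


def calibration_enrichment(
    n_reps: int = 500,
    n_perm: int = 199,
    n_genes: int = 6000,
    seed: int = 0,
) -> dict:
    """Null calibration of the permutation enrichment p-value.

    Replicates draw a uniformly random gene set and read off one bin's
    empirical p-value.  The empirical estimator (1 + #{>= obs}) / (n + 1) is
    mildly conservative when the count statistic takes few values, so the
    calibration study uses large bins and large draws (count standard
    deviation ~15), where the count lattice is fine and the p-value
    distribution is effectively continuous; draw sizes also vary across
    replicates.  Returns the p-values and a Kolmogorov-Smirnov test against
    Uniform(0, 1).
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    n_bins = 5
    size = n_genes // n_bins
    ann = AnnotationMap()
    codes = [f"{j + 1}.1" for j in range(n_bins)]
    for i, g in enumerate(genes):
        ann.gene_to_bins[g] = {codes[i // size]}
    universe = set(genes)

    pvals = np.empty(n_reps)
    for r in range(n_reps):
        k = int(rng.integers(n_genes // 3, n_genes * 3 // 5))
        deg = set(rng.choice(genes, size=k, replace=False))
        res = enrich_bins(deg, ann, universe, n_perm=n_perm, seed=int(rng.integers(2**31)))
        code = codes[r % n_bins]
        pvals[r] = float(res.loc[res["bin"] == code, "p_perm"].iloc[0])
    ks = stats.kstest(pvals, "uniform")
    return {"pvalues": pvals, "ks_stat": float(ks.statistic), "ks_p": float(ks.pvalue)}


def calibration_family_ji(
    n_reps: int = 500,
    n_perm: int = 199,
    n_families: int = 500,
    genes_per_family: int = 3,
    seed: int = 0,
) -> dict:
    """Null calibration of the family-level JI permutation p-value.

    Both species' DEG sets are independent uniform draws (sizes vary per
    replicate), so the observed JI is exchangeable with the shuffled ones
    and the p-values should be uniform.
    """
    rng = np.random.default_rng(seed)
    fams = [f"og{j}" for j in range(n_families)]
    fam_a = AnnotationMap(
        gene_to_family={
            f"Mp{i}": fams[i % n_families] for i in range(n_families * genes_per_family)
        }
    )
    fam_b = AnnotationMap(
        gene_to_family={
            f"At{i}": fams[i % n_families] for i in range(n_families * genes_per_family)
        }
    )
    genes_a = sorted(fam_a.gene_to_family)
    genes_b = sorted(fam_b.gene_to_family)
    pvals = np.empty(n_reps)
    for r in range(n_reps):
        ka = int(rng.integers(200, 600))
        kb = int(rng.integers(200, 600))
        degs_a = {"C": set(rng.choice(genes_a, size=ka, replace=False))}
        degs_b = {"C": set(rng.choice(genes_b, size=kb, replace=False))}
        res = family_deg_ji(
            degs_a, degs_b, fam_a, fam_b, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        pvals[r] = float(res.iloc[0]["p"])
    ks = stats.kstest(pvals, "uniform")
    return {"pvalues": pvals, "ks_stat": float(ks.statistic), "ks_p": float(ks.pvalue)}
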