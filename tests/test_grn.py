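import numpy as np
import pandas as pd
import pytest

from stressatlas.grn import (
    ALL_DATASET,
    STRENGTH_GRID,
    build_networks,
    fit_elasticnet,
    model_quality_curve,
    models_to_frame,
    prepare_slices,
    select_high_confidence,
)


def planted_regression(n, m, active, rng, noise_sd=0.0, coef_scale=1.0):
    """y linear in `active` of m standardized predictors."""
    x = rng.normal(size=(n, m))
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    beta = np.zeros(m)
    for j, b in active.items():
        beta[j] = b * coef_scale
    y = x @ beta + (rng.normal(0, noise_sd, n) if noise_sd else 0.0)
    return y, x, beta


class TestFitElasticnet:
    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(0)
        y, x, beta = planted_regression(30, 5, {1: 2.0, 3: -1.0}, rng)
        model = fit_elasticnet(y, x, cv_folds=3, seed=0)
        assert model.strength == 0.0
        assert model.r2 == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(list(model.coefficients.values()), beta, atol=1e-8)

    def test_pure_noise_prefers_heavy_shrinkage(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(18, 10))
        y = rng.normal(size=18)
        model = fit_elasticnet(y, x, cv_folds=3, seed=0)
        assert model.strength >= 0.1
        # the strongest grid penalty kills every coefficient
        heavy = fit_elasticnet(
            y, x, cv_folds=3, seed=0, strength_grid=(100.0,), mix_grid=(0.5,)
        )
        assert all(c == 0.0 for c in heavy.coefficients.values())

    def test_sparse_support_recovery_at_moderate_noise(self):
        # 3 active of 30 predictors, n=80, signal-to-noise ~5
        hits = 0
        runs = 8
        for seed in range(runs):
            rng = np.random.default_rng(100 + seed)
            active = {2: 1.0, 11: -1.0, 25: 0.8}
            y, x, beta = planted_regression(80, 30, active, rng)
            noise_sd = float(np.std(x @ beta)) / np.sqrt(5.0)
            y = y + rng.normal(0, noise_sd, 80)
            model = fit_elasticnet(y, x, cv_folds=3, seed=0)
            coefs = np.abs(np.array(list(model.coefficients.values())))
            top3 = set(np.argsort(coefs)[-3:])
            hits += top3 == set(active)
        assert hits >= runs - 1

    def test_sample_order_invariance_on_noiseless_data(self):
        rng = np.random.default_rng(2)
        y, x, _ = planted_regression(24, 4, {0: 1.5, 2: 0.5}, rng)
        m1 = fit_elasticnet(y, x, cv_folds=3, seed=0)
        perm = rng.permutation(24)
        m2 = fit_elasticnet(y[perm], x[perm], cv_folds=3, seed=0)
        np.testing.assert_allclose(
            list(m1.coefficients.values()), list(m2.coefficients.values()), atol=1e-8
        )

    def test_coefficient_norm_shrinks_along_strength_grid(self):
        rng = np.random.default_rng(3)
        y, x, _ = planted_regression(40, 8, {0: 2.0, 1: 1.0}, rng, noise_sd=0.5)
        norms = []
        for s in STRENGTH_GRID:
            m = fit_elasticnet(y, x, cv_folds=3, seed=0, strength_grid=(s,), mix_grid=(0.5,))
            norms.append(sum(abs(c) for c in m.coefficients.values()))
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_elasticnet(np.zeros(2), np.zeros((2, 3)), cv_folds=3)


class TestPrepareSlices:
    def test_slice_shapes_and_standardization(self, grn_models, small_bundle):
        slices, _models = grn_models
        design = small_bundle[0]
        assert set(slices) == set(design.single_codes) | {ALL_DATASET}
        dark = slices["D"]
        assert dark.n == 18  # 6 conditions x 3 replicates
        assert slices[ALL_DATASET].n == 81
        z = dark.responses.to_numpy()
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-9)

    def test_predictors_are_the_de_tfs_among_responses(self, grn_models, small_bundle):
        slices, _ = grn_models
        truth = small_bundle[1]
        preds = set(slices[ALL_DATASET].predictors.columns)
        assert preds <= set(truth.tfs)
        assert preds <= set(slices[ALL_DATASET].responses.columns)

    def test_insufficient_samples_error(self, small_bundle, small_degsets):
        design, truth, _lfc, matrix, _de = small_bundle
        with pytest.raises(ValueError, match="cross-validation"):
            prepare_slices(
                matrix, small_degsets, set(truth.tfs), design, stress_cv_folds=20
            )


class TestNetworks:
    def test_model_count_is_responses_times_datasets(self, grn_models):
        slices, models = grn_models
        n_responses = {d: s.responses.shape[1] for d, s in slices.items()}
        assert len(models) == sum(n_responses.values())
        assert len({m.dataset for m in models}) == 8

    def test_r2_filter_is_strict(self):
        frame_models = []
        for r2 in (0.8, 0.8001):
            frame_models.append(
                _dummy_model("g_%s" % r2, "C", {"tf1": 1.0}, r2)
            )
        edges, union = build_networks(frame_models, r2_min=0.8)
        assert set(edges["target"]) == {"g_0.8001"}

    def test_union_is_superset_of_each_dataset(self, grn_models):
        _slices, models = grn_models
        edges, union = build_networks(models, r2_min=0.8)
        union_pairs = set(zip(union["tf"], union["target"]))
        for d in set(union["dataset"]):
            pairs = set(zip(*union.loc[union["dataset"] == d, ["tf", "target"]].T.values))
            assert pairs <= union_pairs
        assert ALL_DATASET not in set(union["dataset"])

    def test_quality_curve_monotone(self, grn_models):
        _slices, models = grn_models
        curve = model_quality_curve(models)
        for col in curve.columns.drop("threshold"):
            assert (curve[col].diff().dropna() <= 0).all()
        assert curve.iloc[0]["ALL"] == sum(1 for m in models if m.dataset == ALL_DATASET)


def _dummy_model(target, dataset, coefs, r2):
    from stressatlas.grn import RegressionModel

    return RegressionModel(
        target=target, dataset=dataset, intercept=0.0, coefficients=coefs,
        mix=0.5, strength=0.1, r2=r2, n=18, cv_mse=0.1,
    )


class TestHighConfidence:
    def test_single_regulator_has_relative_coefficient_one(self):
        models = [_dummy_model("g1", "C", {"tf1": 0.7}, 0.9)]
        hc = select_high_confidence(models_to_frame(models))
        assert hc.iloc[0]["tf"] == "tf1"
        assert hc.iloc[0]["rel_coef"] == pytest.approx(1.0)
        assert hc.iloc[0]["mode"] == "activator"

    def test_relative_coefficient_argmax(self):
        models = [_dummy_model("g1", "C", {"tfA": 2.0, "tfB": -1.0}, 0.9)]
        hc = select_high_confidence(models_to_frame(models))
        assert hc.iloc[0]["tf"] == "tfA"
        assert hc.iloc[0]["rel_coef"] == pytest.approx(2.0 / 3.0)

    def test_sign_conflict_across_datasets_is_ambiguous(self):
        models = [
            _dummy_model("g1", "C", {"tfA": 1.0}, 0.9),
            _dummy_model("g1", "D", {"tfA": -1.0}, 0.9),
        ]
        hc = select_high_confidence(models_to_frame(models))
        assert hc.iloc[0]["mode"] == "ambiguous"

    def test_tie_breaks_to_lexicographically_smallest(self):
        models = [_dummy_model("g1", "C", {"tfB": 1.0, "tfA": -1.0}, 0.9)]
        hc = select_high_confidence(models_to_frame(models))
        assert hc.iloc[0]["tf"] == "tfA"

    def test_out_degree_into_each_target_is_one(self, grn_models):
        _slices, models = grn_models
        _edges, union = build_networks(models, r2_min=0.8)
        hc = select_high_confidence(union)
        assert hc["target"].is_unique

    def test_empty_union_rejected(self):
        with pytest.raises(ValueError):
            select_high_confidence(pd.DataFrame(columns=["dataset", "tf", "target", "coef", "rel_coef", "r2"]))


class TestNoiselessEndToEnd:
    def test_planted_network_recovered_exactly(self, design, noiseless_truth, noiseless_log2fc):
        """Zero-noise planted linear responses: every model is exact and the
        high-confidence regulator is the planted strongest regulator."""
        truth = noiseless_truth
        # regress each regulated target on the planted TFs, noiseless at the
        # log2fc level: the planted log2fc is the expression proxy
        strongest = truth.strongest_regulator()
        conds = list(design.stress_conditions)
        profiles = np.array([noiseless_log2fc[c] for c in conds])  # cond x genes
        gene_idx = {g: i for i, g in enumerate(truth.all_genes)}
        x = profiles[:, [gene_idx[t] for t in truth.tfs]]
        sd = x.std(axis=0)
        keep_tfs = [t for t, s in zip(truth.tfs, sd) if s > 1e-9]
        x = x[:, [i for i, s in enumerate(sd) if s > 1e-9]]
        x = (x - x.mean(axis=0)) / x.std(axis=0)
        regulated = [g for g in strongest if strongest[g] in keep_tfs][:40]
        models = []
        for g in regulated:
            y = profiles[:, gene_idx[g]]
            if y.std() < 1e-9:
                continue
            y = (y - y.mean()) / y.std()
            models.append(
                fit_elasticnet(y, x, cv_folds=3, seed=0, target=g, dataset="ALL",
                               predictor_names=keep_tfs)
            )
        assert models
        exact = [m for m in models if m.r2 > 0.8]
        assert len(exact) == len(models)
        tf_sd = {t: float(profiles[:, gene_idx[t]].std()) for t in keep_tfs}
        agree = sum(
            1 for m in models if _argmax_matches_brute_force(m, truth, tf_sd)
        )
        assert agree == len(models)


def _argmax_matches_brute_force(model, truth, tf_sd):
    """Oracle for the standardized regression: with y = sum_j c_j * TF_j exactly,
    the unique OLS solution on z-scored data has |coef| proportional to
    |c_j| * sd(TF_j), so the argmax regulator follows in closed form."""
    planted = {}
    for tf, gene, coef, _mode in truth.grn_edges:
        if gene == model.target and tf in tf_sd:
            planted[tf] = planted.get(tf, 0.0) + coef * tf_sd[tf]
    if not planted:
        return False
    best_planted = max(planted.items(), key=lambda kv: abs(kv[1]))[0]
    rel = model.relative_coefficients()
    best_fit = max(rel.items(), key=lambda kv: kv[1])[0]
    return best_fit == best_planted
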