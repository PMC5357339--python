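import numpy as np
import pytest
from scipy.special import logsumexp

from sdmrisk import maxent
from sdmrisk.maxent import (
    ModelSettings,
    aicc,
    build_features,
    fit_maxent,
    fit_from_predictors,
    predict_logistic,
    predict_raw,
    replicate_fit,
    response_curve,
    tune_settings,
)


def penalized_objective(lam, F_bg, mean_pres, betas):
    return logsumexp(F_bg @ lam) - mean_pres @ lam + betas @ np.abs(lam)


def grid_search_oracle(F_pres, F_bg, betas, lo=-8.0, hi=8.0, n=81, zooms=6):
    """Independent zoomed dense grid search of the penalized objective."""
    mean_pres = F_pres.mean(axis=0)
    J = F_bg.shape[1]
    lows = np.full(J, lo)
    highs = np.full(J, hi)
    best = None
    for _ in range(zooms):
        axes = [np.linspace(lows[j], highs[j], n) for j in range(J)]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=1)
        vals = np.array([penalized_objective(p, F_bg, mean_pres, betas) for p in pts])
        best = pts[vals.argmin()]
        width = (highs - lows) / (n - 1)
        lows = best - 2 * width
        highs = best + 2 * width
    return best


@pytest.fixture
def small_instance():
    rng = np.random.default_rng(42)
    F_bg = rng.uniform(0, 1, size=(25, 1))
    F_pres = rng.uniform(0.5, 1, size=(10, 1))
    return F_pres, F_bg


class TestBuildFeatures:
    def test_linear_only_counts(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        fs = build_features(X, predictor_names=("a", "b", "c"), classes="L")
        assert fs.n_features == 3

    def test_scaling_endpoints(self):
        X = np.array([[0.0], [2.0], [10.0]])
        fs = build_features(X, predictor_names=("a",), classes="L")
        F = fs.transform(X)
        assert F[0, 0] == 0.0 and F[-1, 0] == 1.0

    def test_lqp_combinatorial_count(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        fs = build_features(X, predictor_names=("a", "b", "c"), classes="LQP")
        assert fs.n_features == 3 + 3 + 3  # linears, squares, distinct pairs

    def test_all_features_unit_interval_on_background(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 3)) * np.array([10.0, 1.0, 500.0])
        fs = build_features(X, predictor_names=("a", "b", "c"), classes="LQPH",
                            n_hinge_knots=20)
        F = fs.transform(X)
        assert F.min() >= 0.0 and F.max() <= 1.0

    def test_hinge_knots_strictly_inside_range(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 1))
        fs = build_features(X, predictor_names=("a",), classes="H", n_hinge_knots=10)
        lo, hi = X.min(), X.max()
        for f in fs.features:
            assert lo < f.knot < hi

    def test_constant_predictor_dropped_with_warning(self):
        X = np.column_stack([np.full(30, 7.0), np.arange(30.0)])
        with pytest.warns(UserWarning, match="constant"):
            fs = build_features(X, predictor_names=("const", "var"), classes="LQ")
        assert fs.dropped == ["const"]
        assert fs.n_features == 2  # only the varying predictor's L and Q

    def test_bad_classes_rejected(self):
        with pytest.raises(ValueError):
            build_features(np.zeros((10, 1)), predictor_names=("a",), classes="LX")


class TestFitMaxent:
    def test_huge_rm_full_shrinkage(self, small_instance):
        F_pres, F_bg = small_instance
        model = fit_maxent(F_pres, F_bg, rm=1e6)
        assert np.all(model.lambdas == 0.0)
        raw = np.exp(F_bg @ model.lambdas - model.log_z)
        np.testing.assert_allclose(raw, 1.0 / len(F_bg))
        assert np.isclose(model.entropy, np.log(len(F_bg)))

    def test_tiny_rm_moment_matching(self, small_instance):
        # unpenalized stationarity: model expectation of f = presence mean of f
        F_pres, F_bg = small_instance
        model = fit_maxent(F_pres, F_bg, rm=1e-8)
        p = np.exp(F_bg @ model.lambdas - model.log_z)
        assert abs(p @ F_bg[:, 0] - F_pres[:, 0].mean()) < 1e-3

    def test_one_feature_matches_grid_search_oracle(self, small_instance):
        F_pres, F_bg = small_instance
        model = fit_maxent(F_pres, F_bg, rm=1.0)
        lam_star = grid_search_oracle(F_pres, F_bg, model.betas)
        assert abs(model.lambdas[0] - lam_star[0]) < 1e-3

    def test_two_features_match_grid_search_oracle(self):
        rng = np.random.default_rng(7)
        F_bg = rng.uniform(0, 1, size=(50, 2))
        F_pres = np.clip(F_bg[rng.choice(50, 12)] + rng.normal(0, 0.1, (12, 2)), 0, 1)
        model = fit_maxent(F_pres, F_bg, rm=1.0)
        lam_star = grid_search_oracle(F_pres, F_bg, model.betas)
        np.testing.assert_allclose(model.lambdas, lam_star, atol=1e-3)

    def test_too_few_presences_rejected(self, small_instance):
        _, F_bg = small_instance
        with pytest.raises(ValueError):
            fit_maxent(F_bg[:4], F_bg, rm=1.0)

    def test_normalization_invariant(self):
        rng = np.random.default_rng(3)
        for seed in range(3):
            rng = np.random.default_rng(seed)
            X_bg = rng.normal(size=(80, 2))
            X_pres = X_bg[rng.choice(80, 15)]
            model = fit_from_predictors(X_pres, X_bg, classes="LQ", rm=1.0)
            raw = predict_raw(model, X_bg)
            assert abs(raw.sum() - 1.0) < 1e-6

    def test_shrinkage_path_monotone(self, small_instance):
        F_pres, F_bg = small_instance
        norms = [
            np.abs(fit_maxent(F_pres, F_bg, rm=rm).lambdas).sum()
            for rm in (0.5, 1.0, 2.0, 4.0, 8.0)
        ]
        for a, b in zip(norms, norms[1:]):
            assert b <= a + 1e-9

    def test_nonconvergence_carries_objective(self, small_instance):
        F_pres, F_bg = small_instance
        with pytest.raises(maxent.ConvergenceError) as exc:
            fit_maxent(F_pres, F_bg, rm=1e-8, max_iter=2)
        assert np.isfinite(exc.value.objective)


class TestPredict:
    def test_uniform_model_raw(self, small_instance):
        F_pres, F_bg = small_instance
        model = fit_maxent(F_pres, F_bg, rm=1e6)
        raw = np.exp(F_bg @ model.lambdas - model.log_z)
        np.testing.assert_allclose(raw, 1.0 / 25)

    def test_raw_monotone_in_predictor(self):
        rng = np.random.default_rng(5)
        X_bg = rng.uniform(0, 10, size=(60, 1))
        X_pres = rng.uniform(7, 10, size=(15, 1))  # presences at high values
        model = fit_from_predictors(X_pres, X_bg, classes="L", rm=0.5)
        assert model.lambdas[0] > 0
        xs = np.linspace(0, 10, 30)[:, None]
        raw = predict_raw(model, xs)
        assert np.all(np.diff(raw) >= 0)

    def test_logistic_uniform_is_half(self, small_instance):
        F_pres, F_bg = small_instance
        model = fit_maxent(F_pres, F_bg, rm=1e6,
                           feature_set=build_features(F_bg, ("f0",), classes="L"),
                           background_X=F_bg)
        lv = predict_logistic(model, F_bg)
        np.testing.assert_allclose(lv, 0.5, atol=1e-12)

    def test_logistic_spot_check_formula(self):
        rng = np.random.default_rng(6)
        X_bg = rng.normal(size=(40, 2))
        X_pres = X_bg[rng.choice(40, 10)]
        model = fit_from_predictors(X_pres, X_bg, classes="LQ", rm=1.0)
        pick = rng.choice(40, 5, replace=False)
        raw = predict_raw(model, X_bg[pick])
        expected = np.exp(model.entropy) * raw / (1 + np.exp(model.entropy) * raw)
        np.testing.assert_allclose(predict_logistic(model, X_bg[pick]), expected, rtol=1e-12)

    def test_logistic_monotone_in_raw(self):
        h = 2.0
        raws = np.linspace(1e-8, 1e-2, 50)
        vals = np.exp(h) * raws / (1 + np.exp(h) * raws)
        assert np.all(np.diff(vals) > 0)


def make_model_with_k(k, n_features=5):
    """Hand-built model wrapper to drive the AICc arithmetic."""
    lam = np.zeros(n_features)
    lam[:k] = 1.0
    fs = build_features(np.linspace(0, 1, 10)[:, None], ("a",), classes="L")
    return maxent.MaxentModel(
        feature_set=fs, lambdas=lam, betas=np.zeros(n_features), rm=1.0,
        log_z=0.0, entropy=0.0, n_background=10,
        background_X=np.empty((0, 1)), n_presence=5,
    )


class TestAICc:
    def test_uniform_closed_form(self):
        C, m = 20, 8
        model = make_model_with_k(0)
        raw_all = np.full(C, 1.0 / C)
        raw_pres = np.full(m, 1.0 / C)
        lnl = m * np.log(1.0 / C)
        assert np.isclose(aicc(model, raw_pres, raw_all), -2.0 * lnl)

    def test_penalty_monotone_in_k(self):
        C, m = 10, 8
        raw_all = np.full(C, 1.0 / C)
        raw_pres = np.full(m, 1.0 / C)  # identical likelihood
        a1 = aicc(make_model_with_k(1), raw_pres, raw_all)
        a2 = aicc(make_model_with_k(2), raw_pres, raw_all)
        assert a2 > a1

    def test_worked_tiny_case(self):
        # C=10 cells, m=5 presences, k=2
        model = make_model_with_k(2)
        raw_all = np.arange(1.0, 11.0)
        raw_pres = np.array([2.0, 5.0, 5.0, 9.0, 10.0])
        lnl = np.sum(np.log(raw_pres / raw_all.sum()))
        expected = 2 * 2 - 2 * lnl + 2 * 2 * 3 / (5 - 2 - 1)
        assert np.isclose(aicc(model, raw_pres, raw_all), expected)

    def test_k_too_large_is_invalid(self):
        model = make_model_with_k(4)
        raw = np.full(5, 0.2)
        assert aicc(model, raw, np.full(10, 0.1)) == float("inf")


class TestTuneSettings:
    @pytest.fixture
    def data(self):
        rng = np.random.default_rng(8)
        X_bg = rng.normal(size=(100, 2)) * [5.0, 1.0]
        X_pres = X_bg[X_bg[:, 0] > 2][:20]
        return X_pres, X_bg

    def test_single_candidate_selected(self, data):
        X_pres, X_bg = data
        res = tune_settings(X_pres, X_bg, candidate_classes=("L",), candidate_rm=(1.0,))
        assert res.selected["classes"] == "L" and res.selected["rm"] == 1.0

    def test_selected_is_argmin(self, data):
        X_pres, X_bg = data
        res = tune_settings(X_pres, X_bg, candidate_classes=("L", "LQ"),
                            candidate_rm=(0.5, 1.0, 2.0))
        finite = [c["aicc"] for c in res.candidates if np.isfinite(c["aicc"])]
        assert res.selected["aicc"] == min(finite)

    def test_all_invalid_raises(self, data, monkeypatch):
        X_pres, X_bg = data
        monkeypatch.setattr(maxent, "aicc", lambda *a, **k: float("inf"))
        with pytest.raises(ValueError, match="invalid"):
            tune_settings(X_pres, X_bg, candidate_classes=("L",), candidate_rm=(1.0,))


class TestReplicateFit:
    def test_single_replicate_equals_direct_prediction(self, bioclim, truth, grid):
        rng = np.random.default_rng(0)
        X_all, flat = bioclim.values_valid()
        pres_idx = rng.choice(len(flat), 40, replace=False)
        X_pres = X_all[pres_idx]
        smap, aucs, models = replicate_fit(
            X_pres, bioclim, ModelSettings(classes="LQ"), n_replicates=1, master_seed=1
        )
        direct = np.full(grid.shape, np.nan)
        direct.ravel()[flat] = predict_logistic(models[0], X_all)
        np.testing.assert_allclose(
            smap.values[grid.valid_mask], direct[grid.valid_mask]
        )

    def test_mean_map_within_replicate_bounds(self, bioclim, grid):
        rng = np.random.default_rng(1)
        X_all, flat = bioclim.values_valid()
        X_pres = X_all[rng.choice(len(flat), 40, replace=False)]
        smap, _, models = replicate_fit(
            X_pres, bioclim, ModelSettings(classes="LQ"), n_replicates=3, master_seed=2
        )
        per = np.stack([predict_logistic(m, X_all) for m in models])
        mean_vals = smap.values[grid.valid_mask]
        assert np.all(mean_vals >= per.min(axis=0) - 1e-12)
        assert np.all(mean_vals <= per.max(axis=0) + 1e-12)

    def test_determinism_same_master_seed(self, bioclim, grid):
        rng = np.random.default_rng(2)
        X_all, flat = bioclim.values_valid()
        X_pres = X_all[rng.choice(len(flat), 40, replace=False)]
        out1 = replicate_fit(X_pres, bioclim, ModelSettings(classes="LQ"),
                             n_replicates=3, master_seed=7)
        out2 = replicate_fit(X_pres, bioclim, ModelSettings(classes="LQ"),
                             n_replicates=3, master_seed=7)
        np.testing.assert_array_equal(
            out1[0].values[grid.valid_mask], out2[0].values[grid.valid_mask]
        )
        assert out1[1] == out2[1]

    def test_too_few_presences_rejected(self, bioclim):
        X_pres = bioclim.values_valid()[0][:5]
        with pytest.raises(ValueError):
            replicate_fit(X_pres, bioclim, n_replicates=2)


class TestResponseCurve:
    def test_flat_when_coefficient_zero(self):
        rng = np.random.default_rng(9)
        X_bg = rng.normal(size=(50, 2))
        X_pres = X_bg[rng.choice(50, 10)]
        model = fit_from_predictors(X_pres, X_bg, classes="L", rm=1e6)
        _, curve = response_curve(model, "p0")
        np.testing.assert_allclose(curve, curve[0])

    def test_monotone_for_positive_linear(self):
        rng = np.random.default_rng(10)
        X_bg = rng.uniform(0, 10, size=(60, 2))
        X_pres = np.column_stack([rng.uniform(8, 10, 15), rng.uniform(0, 10, 15)])
        model = fit_from_predictors(X_pres, X_bg, classes="L", rm=0.5)
        assert model.lambdas[0] > 0
        _, curve = response_curve(model, "p0")
        assert np.all(np.diff(curve) >= -1e-12)

    def test_endpoints_match_direct_prediction(self):
        rng = np.random.default_rng(11)
        X_bg = rng.normal(size=(50, 2))
        X_pres = X_bg[rng.choice(50, 10)]
        model = fit_from_predictors(X_pres, X_bg, classes="LQ", rm=1.0)
        xs, curve = response_curve(model, "p1", n_points=10)
        mean = X_bg.mean(axis=0)
        for idx in (0, -1):
            X = mean.copy()
            X[1] = xs[idx]
            assert np.isclose(curve[idx], predict_logistic(model, X[None, :])[0])

    def test_unknown_predictor_rejected(self):
        rng = np.random.default_rng(12)
        X_bg = rng.normal(size=(50, 1))
        model = fit_from_predictors(X_bg[:10], X_bg, classes="L", rm=1.0)
        with pytest.raises(KeyError):
            response_curve(model, "nope")
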