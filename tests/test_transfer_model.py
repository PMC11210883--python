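import numpy as np
import pytest

from tfmirror.transfer_model import (
    BoostingConfig,
    TransferFunctionModel,
    fit,
    forecast,
    partial_dependence_profile,
    predict_one_step,
    screen_interactions,
)
from tfmirror.ts_data import LaggedDesign, StudyCollection, tile_windows

from conftest import make_collection


def make_design(X, Y, P=1, Q=1, n_base=None, interactions=None, names=None):
    n, d = X.shape
    interactions = interactions or []
    n_base = n_base if n_base is not None else d - len(interactions)
    names = names or [f"f{i}" for i in range(d)]
    return LaggedDesign(
        X=X,
        Y_response=Y if Y.ndim == 2 else Y[:, None],
        window_index=[("A", float(i)) for i in range(n)],
        P=P,
        Q=Q,
        feature_names=names,
        n_base=n_base,
        interactions=interactions,
    )


def linear_model(coefs, intercept=0.0, P=1, Q=1, J=1, D=1, S=0, interactions=None):
    """Hand-built model with known coefficients for a single taxon or many."""
    interactions = interactions or []
    n_base = P * J + Q * D + S
    d = n_base + len(interactions)
    coefs = np.asarray(coefs, dtype=float)
    if coefs.ndim == 1:
        coefs = coefs[:, None]
    J_out = coefs.shape[1]
    return TransferFunctionModel(
        intercepts=np.full(J_out, intercept),
        coefficients=coefs,
        P=P,
        Q=Q,
        interactions=interactions,
        feature_names=[f"f{i}" for i in range(d)],
        n_base=n_base,
        taxa=[f"tax{j + 1}" for j in range(J)][:J_out] if J >= J_out
        else [f"tax{j + 1}" for j in range(J_out)],
        intervention_names=[f"w{k + 1}" for k in range(D)],
        covariate_names=[f"z{k + 1}" for k in range(S)],
    )


class TestScreening:
    def _product_instance(self, seed=0, n=200, d=5):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, d))
        y = X[:, 1] * X[:, 2] + 0.05 * rng.normal(size=n)
        return X, y

    def test_exhaustive_finds_product_pair(self):
        X, y = self._product_instance()
        design = make_design(X, y)
        cfg = BoostingConfig(screen_method="exhaustive", max_interactions=3)
        pairs = screen_interactions(design, config=cfg)
        assert pairs[0] == (1, 2)

    def test_none_returns_empty(self):
        X, y = self._product_instance()
        design = make_design(X, y)
        cfg = BoostingConfig(screen_method="none")
        assert screen_interactions(design, config=cfg) == []

    def test_random_projection_vs_exhaustive_oracle(self):
        # the randomized screener should contain the exhaustive winner in
        # >= 95% of seeds
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            X, y = self._product_instance(seed=seed)
            design = make_design(X, y)
            cfg = BoostingConfig(
                screen_method="xyz_random_projection",
                max_interactions=3,
                n_projections=50,
                random_seed=seed,
            )
            pairs = screen_interactions(design, config=cfg)
            hits += (1, 2) in pairs
        assert hits / n_seeds >= 0.95

    def test_constant_response_skipped(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 4))
        Y = np.column_stack([np.full(50, 2.0), X[:, 0] * X[:, 1]])
        design = make_design(X, Y)
        cfg = BoostingConfig(screen_method="exhaustive", max_interactions=2)
        pairs = screen_interactions(design, config=cfg)
        assert (0, 1) in pairs


class TestFit:
    def test_single_feature_exact(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=60)
        y = 3.0 * x + 1.0
        X = np.column_stack([x])
        design = make_design(X, y)
        cfg = BoostingConfig(n_iterations=1, learning_rate=1.0, screen_method="none",
                             max_interactions=0)
        model = fit(design, config=cfg)
        assert model.coefficients[0, 0] == pytest.approx(3.0, rel=1e-10)
        resid = model.predict_design(X)[:, 0] - y
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_zero_iterations_predicts_means(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3))
        Y = rng.normal(size=(40, 2)) + np.array([5.0, -2.0])
        design = make_design(X, Y)
        cfg = BoostingConfig(n_iterations=0, screen_method="none", max_interactions=0)
        model = fit(design, config=cfg)
        pred = model.predict_design(X)
        np.testing.assert_allclose(pred, Y.mean(axis=0)[None, :].repeat(40, axis=0))

    def test_boosting_approaches_ols(self):
        # y = 2 x3 + noise; coefficient within 5% of closed-form OLS
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 5))
        y = 2.0 * X[:, 3] + 0.3 * rng.normal(size=200)
        design = make_design(X, y)
        cfg = BoostingConfig(n_iterations=500, learning_rate=0.1, screen_method="none",
                             max_interactions=0)
        model = fit(design, config=cfg)
        X1 = np.column_stack([np.ones(200), X])
        beta_ols = np.linalg.lstsq(X1, y, rcond=None)[0]
        assert model.coefficients[3, 0] == pytest.approx(beta_ols[4], rel=0.05)

    def test_training_error_monotone(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 6))
        y = X @ rng.normal(size=6) + 0.5 * rng.normal(size=80)
        design = make_design(X, y)
        errs = []
        for n_iter in (0, 1, 5, 20, 100, 300):
            cfg = BoostingConfig(n_iterations=n_iter, learning_rate=0.1,
                                 screen_method="none", max_interactions=0)
            model = fit(design, config=cfg)
            errs.append(float(np.mean((model.predict_design(X)[:, 0] - y) ** 2)))
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))

    def test_constant_columns_never_selected(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([np.full(50, 3.0), rng.normal(size=50)])
        y = 2.0 * X[:, 1]
        design = make_design(X, y)
        cfg = BoostingConfig(n_iterations=100, learning_rate=0.5, screen_method="none",
                             max_interactions=0)
        model = fit(design, config=cfg)
        assert model.coefficients[0, 0] == 0.0

    def test_row_order_invariance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 4))
        Y = rng.normal(size=(60, 3))
        design = make_design(X, Y)
        cfg = BoostingConfig(n_iterations=50, screen_method="none", max_interactions=0)
        model = fit(design, config=cfg)
        perm = rng.permutation(60)
        design_p = make_design(X[perm], Y[perm])
        model_p = fit(design_p, config=cfg)
        np.testing.assert_allclose(model.coefficients, model_p.coefficients, atol=1e-10)
        probe = rng.normal(size=(5, 4))
        np.testing.assert_allclose(
            model.predict_design(probe), model_p.predict_design(probe), atol=1e-10
        )

    def test_parameter_sign_recovery(self):
        # sparse linear lag-1 model: signs of large coefficients recovered
        rng = np.random.default_rng(6)
        n_subj, T, J = 50, 20, 4
        beta = np.zeros((J, J))
        beta[0, 1] = 1.5
        beta[2, 3] = -1.2
        beta[1, 1] = 0.8
        coll = make_collection(n_subjects=n_subj, J=J, T=T, seed=7)
        for s in coll.subjects:
            y = np.zeros((J, T))
            y[:, 0] = rng.normal(size=J)
            for t in range(1, T):
                y[:, t] = beta @ y[:, t - 1] + 0.3 * rng.normal(size=J)
            coll.abundances[s] = y
        design = tile_windows(coll, P=1, Q=1)
        cfg = BoostingConfig(n_iterations=500, learning_rate=0.1, screen_method="none",
                             max_interactions=0)
        model = fit(design, config=cfg, taxa=coll.taxa)
        for j, k, b in [(0, 1, 1.5), (2, 3, -1.2), (1, 1, 0.8)]:
            # feature k at lag 1 is column k of the design
            assert np.sign(model.coefficients[k, j]) == np.sign(b)


class TestPredict:
    def test_known_coefficients_dot_product(self):
        coefs = np.column_stack([[0.5, -1.0, 2.0], [0.0, 0.0, 0.0]])
        model = linear_model(coefs, intercept=0.7, P=1, Q=1, J=2, D=1)
        Y_hist = np.array([[3.0], [4.0]])
        W_hist = np.array([[1.0]])
        out = predict_one_step(model, Y_hist, W_hist)
        expected = 0.7 + 0.5 * 3.0 - 1.0 * 4.0 + 2.0 * 1.0
        assert out[0] == pytest.approx(expected, rel=1e-12)
        assert out[1] == pytest.approx(0.7, rel=1e-12)

    def test_shape_mismatch_reports_dims(self):
        coefs = np.zeros((3, 2))
        model = linear_model(coefs, P=1, Q=1, J=2, D=1)
        with pytest.raises(ValueError, match="J=2, P=1"):
            predict_one_step(model, np.zeros((3, 1)), np.zeros((1, 1)))

    def test_intercept_only(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 2))
        Y = rng.normal(size=(30, 1)) + 4.0
        design = make_design(X, Y)
        cfg = BoostingConfig(n_iterations=0, screen_method="none", max_interactions=0)
        model = fit(design, config=cfg)
        np.testing.assert_allclose(
            model.predict_design(rng.normal(size=(7, 2))), Y.mean(), rtol=1e-12
        )


def ar1_collection(phi=0.5, y0=8.0, T=12):
    y = y0 * phi ** np.arange(T)
    return StudyCollection(
        subjects=["A"],
        abundances={"A": y[None, :]},
        interventions={"A": np.zeros((1, T))},
        covariates={"A": np.zeros(0)},
        taxa=["tax1"],
        intervention_names=["w1"],
        covariate_names=[],
        time_grid={"A": np.arange(T, dtype=float)},
    )


class TestForecast:
    def _ar1_model(self):
        coll = ar1_collection()
        design = tile_windows(coll, P=1, Q=1)
        cfg = BoostingConfig(n_iterations=5, learning_rate=1.0, screen_method="none",
                             max_interactions=0)
        return fit(design, config=cfg, taxa=coll.taxa), coll

    def test_ar1_closed_form(self):
        model, coll = self._ar1_model()
        # truncate so the last observation is y = 8 * 0.5^0 = 8
        obs = coll.truncate(1)
        # need >= P observations: P = 1, fine
        pred = forecast(model, obs, np.zeros((1, 3)), 3)["A"]
        np.testing.assert_allclose(pred[0], [4.0, 2.0, 1.0], atol=1e-6)

    def test_h1_equals_one_step(self):
        model, coll = self._ar1_model()
        obs = coll.truncate(5)
        f1 = forecast(model, obs, np.zeros((1, 1)), 1)["A"][:, 0]
        one = predict_one_step(
            model,
            obs.abundances["A"][:, -1:],
            np.zeros((1, 1)),
        )
        assert f1[0] == one[0]  # bit-identical

    def test_zero_coefficient_model_constant(self):
        model = linear_model([0.0, 0.0], intercept=2.5, P=1, Q=1, J=1, D=1)
        coll = ar1_collection()
        pred = forecast(model, coll, np.zeros((1, 4)), 4)["A"]
        np.testing.assert_allclose(pred, 2.5)

    def test_horizon_validation(self):
        model, coll = self._ar1_model()
        with pytest.raises(ValueError, match="horizon"):
            forecast(model, coll, np.zeros((1, 0)), 0)

    def test_missing_future_interventions(self):
        model, coll = self._ar1_model()
        with pytest.raises(ValueError, match="future interventions"):
            forecast(model, coll, {}, 2)

    def test_substitution_uses_observed_history(self):
        # with P=2, the first forecast step must mix the two observed values
        coll = make_collection(n_subjects=1, J=2, T=10, seed=11)
        design = tile_windows(coll, P=2, Q=1)
        cfg = BoostingConfig(n_iterations=50, screen_method="none", max_interactions=0)
        model = fit(design, config=cfg, taxa=coll.taxa)
        obs = coll.truncate(6)
        pred = forecast(model, obs, np.zeros((1, 2)), 2)["A" if "A" in obs.subjects else "S1"]
        manual1 = predict_one_step(
            model, obs.abundances["S1"][:, 4:6], np.zeros((1, 1))
        )
        np.testing.assert_allclose(pred[:, 0], manual1, atol=1e-12)


class TestPartialDependence:
    def test_linear_profile_slope(self):
        rng = np.random.default_rng(0)
        model = linear_model([1.5, 0.0, -0.3], P=1, Q=1, J=2, D=1)
        X = rng.normal(size=(50, 3))
        design = make_design(X, rng.normal(size=(50, 1)), n_base=3)
        grid = np.linspace(-2, 2, 5)
        prof = partial_dependence_profile(model, 0, 0, grid, design)
        slopes = np.diff(prof) / np.diff(grid)
        np.testing.assert_allclose(slopes, 1.5, rtol=1e-10)

    def test_interaction_strata_slopes(self):
        # f = 2*x0 + 1*x1 + 0.5*x0*x1; profile slope of x0 at fixed x1 = b
        # is 2 + 0.5*b, so two strata differ by 0.5 * (b2 - b1)
        rng = np.random.default_rng(1)
        model = linear_model([2.0, 1.0, 0.0, 0.5], P=1, Q=1, J=2, D=1,
                             interactions=[(0, 1)])
        grid = np.array([0.0, 1.0])
        slopes = {}
        for b in (0.0, 2.0):
            X = rng.normal(size=(40, 3))
            X[:, 1] = b
            Xfull = np.hstack([X, (X[:, 0] * X[:, 1])[:, None]])
            design = make_design(Xfull, rng.normal(size=(40, 1)), n_base=3,
                                 interactions=[(0, 1)])
            prof = partial_dependence_profile(model, 0, 0, grid, design)
            slopes[b] = prof[1] - prof[0]
        assert slopes[2.0] - slopes[0.0] == pytest.approx(0.5 * 2.0, rel=1e-10)

    def test_constant_model_flat(self):
        rng = np.random.default_rng(2)
        model = linear_model([0.0, 0.0, 0.0], intercept=3.3, P=1, Q=1, J=2, D=1)
        X = rng.normal(size=(20, 3))
        design = make_design(X, rng.normal(size=(20, 1)), n_base=3)
        prof = partial_dependence_profile(model, 0, 1, np.linspace(-1, 1, 4), design)
        np.testing.assert_allclose(prof, 3.3, rtol=1e-12)

    def test_empty_grid_errors(self):
        model = linear_model([1.0, 0.0, 0.0], P=1, Q=1, J=2, D=1)
        X = np.zeros((5, 3))
        design = make_design(X, np.zeros((5, 1)), n_base=3)
        with pytest.raises(ValueError, match="grid"):
            partial_dependence_profile(model, 0, 0, [], design)


class TestSerialization:
    def test_save_load_roundtrip(self, tmp_path):
        coll = make_collection(n_subjects=2, J=3, T=10, seed=8)
        design = tile_windows(coll, P=2, Q=1, interactions=[(0, 2)])
        cfg = BoostingConfig(n_iterations=30, screen_method="none", max_interactions=0)
        model = fit(design, config=cfg, taxa=coll.taxa,
                    intervention_names=coll.intervention_names, covariate_names=[])
        path = tmp_path / "model.json"
        model.save(str(path))
        back = type(model).load(str(path))
        np.testing.assert_allclose(back.coefficients, model.coefficients)
        np.testing.assert_allclose(back.intercepts, model.intercepts)
        assert back.taxa == model.taxa
        assert back.interactions == model.interactions
        probe = np.random.default_rng(0).normal(size=(4, design.n_base))
        np.testing.assert_allclose(
            back.predict_base_rows(probe), model.predict_base_rows(probe)
        )
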