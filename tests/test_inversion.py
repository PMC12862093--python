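import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm_api

from smveg import inversion as inv
from smveg import synthetic as syn
from smveg.grid import BasinGeometry, RasterGrid


def table_from(X: dict, sm, depth="0-10"):
    n = len(sm)
    df = pd.DataFrame(X)
    df.insert(0, "site", np.arange(n))
    df.insert(1, "x", 0.0)
    df.insert(2, "y", 0.0)
    df.insert(3, "depth", depth)
    df["SM"] = sm
    return df


class TestScreening:
    def test_exact_copy_retained_with_r_one(self, rng):
        y = rng.uniform(0.1, 0.9, 50)
        df = table_from({"copy": y, "noise": rng.standard_normal(50)}, y)
        out = inv.screen_predictors(df, "0-10")
        assert out.loc["copy", "r"] == pytest.approx(1.0)
        assert bool(out.loc["copy", "retained"])

    def test_anticorrelated_retained_two_sided(self, rng):
        y = rng.uniform(0.1, 0.9, 50)
        df = table_from({"anti": -y, "noise": rng.standard_normal(50)}, y)
        out = inv.screen_predictors(df, "0-10")
        assert out.loc["anti", "r"] == pytest.approx(-1.0)
        assert bool(out.loc["anti", "retained"])

    def test_constant_predictor_excluded(self, rng):
        y = rng.uniform(0.1, 0.9, 50)
        df = table_from({"const": np.ones(50), "z": rng.standard_normal(50)}, y)
        out = inv.screen_predictors(df, "0-10")
        assert "const" not in out.index


class TestSplit:
    def test_170_sites_split_136_34(self):
        df = table_from({"a": np.zeros(170)}, np.zeros(170))
        train, valid = inv.split_samples(df, (4, 1), seed=1)
        assert (len(train), len(valid)) == (136, 34)

    def test_20_sites_split_16_4(self):
        df = table_from({"a": np.zeros(20)}, np.zeros(20))
        train, valid = inv.split_samples(df, (4, 1), seed=1)
        assert (len(train), len(valid)) == (16, 4)

    def test_seeded_and_disjoint(self):
        df = table_from({"a": np.zeros(50)}, np.zeros(50))
        t1, v1 = inv.split_samples(df, (4, 1), seed=7)
        t2, v2 = inv.split_samples(df, (4, 1), seed=7)
        assert set(t1["site"]) == set(t2["site"])
        assert not (set(t1["site"]) & set(v1["site"]))


class TestStepwise:
    def test_zero_noise_recovers_printed_surface_equation(self):
        """Noise-free truth -> exact coefficient recovery (1e-6)."""
        truth = syn.TruthConfig(noise_sd=0.0, seed=5)
        table = syn.generate_soil_samples(170, truth)
        train = table[table["depth"] == "0-10"]
        model = inv.fit_smlr(train, ["P_cap", "BD", "P_non", "TN", "TP"], "0-10")
        assert set(model.coefficients) == {"P_cap", "BD"}
        assert model.intercept == pytest.approx(-0.105, abs=1e-6)
        assert model.coefficients["P_cap"] == pytest.approx(0.013, abs=1e-6)
        assert model.coefficients["BD"] == pytest.approx(0.084, abs=1e-6)

    def test_true_pair_selected_under_light_noise(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 136
            p_cap = rng.uniform(30, 60, n)
            bd = rng.uniform(0.9, 1.6, n)
            noise = {f"n{i}": rng.standard_normal(n) for i in range(3)}
            y = -0.105 + 0.013 * p_cap + 0.084 * bd + rng.normal(0, 0.001, n)
            df = table_from({"P_cap": p_cap, "BD": bd, **noise}, y)
            model = inv.fit_smlr(df, ["P_cap", "BD", *noise], "0-10")
            hits += {"P_cap", "BD"} <= set(model.coefficients)
        assert hits >= 19

    def test_pure_noise_mostly_intercept_only(self):
        intercept_only = 0
        for seed in range(40):
            rng = np.random.default_rng(1000 + seed)
            n = 100
            df = table_from(
                {f"n{i}": rng.standard_normal(n) for i in range(2)},
                rng.uniform(0.2, 0.6, n),
            )
            model = inv.fit_smlr(df, ["n0", "n1"], "0-10")
            intercept_only += not model.coefficients
        # about 1 - alpha of null fits should stay empty
        assert intercept_only >= 32

    def test_matches_exhaustive_stable_subset(self):
        """Stepwise lands on the same subset as exhaustive search over all
        significance-stable subsets (<= 6 candidates, equal entry/removal
        gates so the stable subset is unique)."""
        alpha = 0.05
        for seed in range(6):
            rng = np.random.default_rng(seed)
            n = 120
            X = rng.standard_normal((n, 6))
            y = 0.5 + 0.8 * X[:, 0] - 0.6 * X[:, 1] + rng.normal(0, 0.3, n)
            names = [f"p{i}" for i in range(6)]
            df = table_from(dict(zip(names, X.T)), y)
            model = inv.fit_smlr(df, names, "0-10", p_enter=alpha, p_remove=alpha)

            best, best_r2 = None, -np.inf
            for k in range(0, 7):
                for subset in itertools.combinations(range(6), k):
                    Xs = sm_api.add_constant(X[:, list(subset)]) if subset else np.ones((n, 1))
                    fit = sm_api.OLS(y, Xs).fit()
                    if subset and (fit.pvalues[1:] > alpha).any():
                        continue  # removal gate violated
                    excluded = [j for j in range(6) if j not in subset]
                    enters = False
                    for j in excluded:
                        Xj = sm_api.add_constant(np.column_stack([X[:, list(subset)], X[:, j]]))
                        if sm_api.OLS(y, Xj).fit().pvalues[-1] < alpha:
                            enters = True
                            break
                    if enters:
                        continue  # entry gate violated: not a stopping point
                    if fit.rsquared > best_r2:
                        best, best_r2 = set(subset), fit.rsquared
            assert {names[j] for j in best} == set(model.coefficients)


class TestRidgeAndPls:
    @pytest.fixture
    def design(self, rng):
        n = 80
        X = rng.standard_normal((n, 3))
        y = 0.3 + 0.5 * X[:, 0] - 0.2 * X[:, 1] + 0.1 * X[:, 2] + rng.normal(0, 0.05, n)
        names = ["a", "b", "c"]
        return table_from(dict(zip(names, X.T)), y), names, X, y

    def test_zero_penalty_equals_ols(self, design):
        df, names, X, y = design
        model = inv.fit_ridge(df, names, penalty=0.0)
        ols = sm_api.OLS(y, sm_api.add_constant(X)).fit()
        assert model.intercept == pytest.approx(ols.params[0], abs=1e-8)
        for name, coef in zip(names, ols.params[1:]):
            assert model.coefficients[name] == pytest.approx(coef, abs=1e-8)

    def test_infinite_penalty_shrinks_to_mean(self, design):
        df, names, _, y = design
        model = inv.fit_ridge(df, names, penalty=1e12)
        assert all(abs(c) < 1e-6 for c in model.coefficients.values())
        assert model.intercept == pytest.approx(y.mean(), abs=1e-6)

    def test_duplicated_predictors_share_weight(self, rng):
        n = 60
        x = rng.standard_normal(n)
        y = 0.2 + 0.8 * x + rng.normal(0, 0.02, n)
        df = table_from({"a": x, "b": x.copy()}, y)
        model = inv.fit_ridge(df, ["a", "b"], penalty=1.0)
        assert model.coefficients["a"] == pytest.approx(model.coefficients["b"], rel=1e-8)

    def test_full_components_pls_equals_ols(self, design):
        df, names, X, y = design
        model = inv.fit_plsr(df, names, n_components=3)
        ols = sm_api.OLS(y, sm_api.add_constant(X)).fit()
        pred_pls = model.predict(df)
        pred_ols = ols.predict(sm_api.add_constant(X))
        np.testing.assert_allclose(pred_pls, pred_ols, atol=1e-8)

    def test_single_latent_factor_selects_one_component(self):
        picks = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 100
            t = rng.standard_normal(n)
            X = np.column_stack([t + rng.normal(0, 0.1, n) for _ in range(4)])
            y = 0.5 * t + rng.normal(0, 0.1, n)
            df = table_from(dict(zip("abcd", X.T)), y)
            model = inv.fit_plsr(df, list("abcd"), seed=seed)
            picks += model.hyperparameters["n_components"] == 1
        assert picks >= 9

    def test_single_predictor_pls_matches_simple_regression(self, rng):
        n = 50
        x = rng.standard_normal(n)
        y = 1.0 + 2.0 * x + rng.normal(0, 0.1, n)
        df = table_from({"a": x}, y)
        model = inv.fit_plsr(df, ["a"], n_components=1)
        slope = np.cov(x, y)[0, 1] / x.var(ddof=1)
        assert model.coefficients["a"] == pytest.approx(slope, rel=1e-8)


class TestMetricsAndSelection:
    def test_perfect_predictions(self):
        df = table_from({"a": np.array([1.0, 2.0, 3.0])}, [0.2, 0.4, 0.6])
        model = inv.FittedModel("SMLR", "0-10", 0.0, {"a": 0.2})
        rep = inv.evaluate(model, df)
        assert rep.rmse == pytest.approx(0.0, abs=1e-12)
        assert rep.mae == pytest.approx(0.0, abs=1e-12)
        assert rep.mape == pytest.approx(0.0, abs=1e-9)
        assert rep.r2 == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        df = table_from({"a": np.array([0.0, 0.0])}, [0.2, 0.4])
        model = inv.FittedModel("SMLR", "0-10", 0.3, {})
        rep = inv.evaluate(model, df)
        assert rep.rmse == pytest.approx(0.1)
        assert rep.mae == pytest.approx(0.1)
        assert rep.mape == pytest.approx((50.0 + 25.0) / 2)

    def test_mean_prediction_gives_zero_r2(self, rng):
        y = rng.uniform(0.2, 0.8, 30)
        df = table_from({"a": np.zeros(30)}, y)
        model = inv.FittedModel("SMLR", "0-10", float(y.mean()), {})
        rep = inv.evaluate(model, df)
        assert rep.r2 == pytest.approx(0.0, abs=1e-12)
        assert rep.rmse >= rep.mae

    def _report(self, method, rmse, mae, mape, r2):
        return inv.EvaluationReport(method, "0-10", r2, rmse, mae, mape, 0.001, 100, 25)

    def test_gate_thresholds(self):
        assert self._report("SMLR", 0.03, 0.01, 10.0, 0.9).passes_gates()
        assert not self._report("SMLR", 0.06, 0.01, 10.0, 0.9).passes_gates()

    def test_single_passing_candidate_wins_regardless_of_r2(self):
        passing = self._report("PLSR", 0.03, 0.01, 10.0, 0.5)
        failing = self._report("SMLR", 0.08, 0.05, 30.0, 0.99)
        best, flags = inv.select_model([failing, passing])
        assert best.method == "PLSR" and not flags

    def test_max_r2_among_passing(self):
        a = self._report("SMLR", 0.03, 0.01, 10.0, 0.97)
        b = self._report("Ridge", 0.03, 0.01, 10.0, 0.96)
        best, _ = inv.select_model([a, b])
        assert best.method == "SMLR"

    def test_no_passing_falls_back_to_min_rmse_flagged(self):
        a = self._report("SMLR", 0.08, 0.05, 30.0, 0.9)
        b = self._report("Ridge", 0.07, 0.05, 30.0, 0.8)
        best, flags = inv.select_model([a, b])
        assert best.method == "Ridge" and flags


class TestRasterPrediction:
    def test_printed_equations_hand_values(self, open_geometry):
        grids = {
            "P_cap": RasterGrid(np.full(open_geometry.shape, 50.0), open_geometry),
            "BD": RasterGrid(np.full(open_geometry.shape, 1.3), open_geometry),
        }
        model = inv.FittedModel("SMLR", "0-10", -0.105, {"P_cap": 0.013, "BD": 0.084})
        out = inv.predict_raster(model, grids, clip=None)
        np.testing.assert_allclose(out.values, 0.6542, atol=1e-12)

        grids = {
            "P_cap": RasterGrid(np.full(open_geometry.shape, 40.0), open_geometry),
            "BD": RasterGrid(np.full(open_geometry.shape, 1.2), open_geometry),
        }
        model = inv.FittedModel("SMLR", "20-30", -0.115, {"P_cap": 0.013, "BD": 0.091})
        out = inv.predict_raster(model, grids, clip=None)
        np.testing.assert_allclose(out.values, 0.5142, atol=1e-12)

    def test_nodata_propagates(self, open_geometry):
        a = np.full(open_geometry.shape, 50.0)
        a[2, 2] = np.nan
        grids = {
            "P_cap": RasterGrid(a, open_geometry),
            "BD": RasterGrid(np.full(open_geometry.shape, 1.3), open_geometry),
        }
        model = inv.FittedModel("SMLR", "0-10", -0.105, {"P_cap": 0.013, "BD": 0.084})
        out = inv.predict_raster(model, grids)
        assert np.isnan(out.data[2, 2]) and np.isfinite(out.data[0, 0])

    def test_missing_grid_is_an_error(self, open_geometry):
        model = inv.FittedModel("SMLR", "0-10", -0.105, {"P_cap": 0.013, "BD": 0.084})
        with pytest.raises(KeyError, match="BD"):
            inv.predict_raster(
                model,
                {"P_cap": RasterGrid(np.full(open_geometry.shape, 50.0), open_geometry)},
            )

    def test_idw_interpolates_exactly_at_sites(self):
        geom = BasinGeometry(10, 10, 20.0)
        df = pd.DataFrame(
            {"site": [0, 1], "x": [30.0, 150.0], "y": [-30.0, -150.0], "BD": [1.0, 1.5]}
        )
        surf = inv.idw_surface(df, "BD", geom)
        assert surf.data[1, 1] == pytest.approx(1.0)
        assert surf.data[7, 7] == pytest.approx(1.5)
        assert np.nanmin(surf.data) >= 1.0 - 1e-9
        assert np.nanmax(surf.data) <= 1.5 + 1e-9
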