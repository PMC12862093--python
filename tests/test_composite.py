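import numpy as np
import pandas as pd
import pytest

from smveg import composite as comp
from smveg.grid import RasterGrid


def equicorrelated(p, r):
    return np.full((p, p), r) + (1 - r) * np.eye(p)


class TestKmo:
    def test_identity_matrix_degenerate(self):
        assert comp.kmo(np.eye(3)) == 0.0

    def test_matches_brute_force_partial_correlations(self, rng):
        """Anti-image formula against partial correlations computed by
        residualizing each pair on the remaining variables."""
        X = rng.standard_normal((200, 4))
        X[:, 1] += 0.7 * X[:, 0]
        X[:, 2] += 0.4 * X[:, 0] - 0.3 * X[:, 1]
        R = np.corrcoef(X, rowvar=False)
        p = R.shape[0]
        r2 = q2 = 0.0
        for i in range(p):
            for j in range(p):
                if i == j:
                    continue
                others = [k for k in range(p) if k not in (i, j)]
                A = np.column_stack([X[:, others], np.ones(len(X))])
                ri = X[:, i] - A @ np.linalg.lstsq(A, X[:, i], rcond=None)[0]
                rj = X[:, j] - A @ np.linalg.lstsq(A, X[:, j], rcond=None)[0]
                q2 += np.corrcoef(ri, rj)[0, 1] ** 2
                r2 += R[i, j] ** 2
        expected = r2 / (r2 + q2)
        assert comp.kmo(R) == pytest.approx(expected, abs=1e-10)

    def test_equicorrelated_limit_approaches_one(self):
        # anti-image partials of an equicorrelated matrix are r/(1+(p-2)r),
        # so the r -> 1 limit of KMO is 1/(1 + 1/(p-1)^2): it approaches 1
        # with dimension (p=3 saturates at 0.8, p=20 exceeds 0.99)
        low = comp.kmo(equicorrelated(3, 0.8))
        high = comp.kmo(equicorrelated(3, 0.999))
        assert 0.0 < low < high
        assert high == pytest.approx(0.8, abs=5e-3)
        assert comp.kmo(equicorrelated(20, 0.999)) > 0.99


class TestBartlett:
    def test_identity_gives_zero_statistic(self):
        chi2, df, p = comp.bartlett(np.eye(3), 100)
        assert chi2 == pytest.approx(0.0)
        assert df == 3
        assert p == pytest.approx(1.0)

    def test_equicorrelated_matches_closed_form_determinant(self):
        # |R| = (1 - r)^(p-1) (1 + (p-1) r) for an equicorrelated matrix
        r, p_vars, n = 0.6, 3, 100
        chi2, df, _ = comp.bartlett(equicorrelated(p_vars, r), n)
        det = (1 - r) ** (p_vars - 1) * (1 + (p_vars - 1) * r)
        expected = -(n - 1 - (2 * p_vars + 5) / 6) * np.log(det)
        assert chi2 == pytest.approx(expected, rel=1e-12)
        assert df == 3

    def test_requires_enough_observations(self):
        with pytest.raises(ValueError):
            comp.bartlett(np.eye(3), 3)


class TestPca:
    def test_loadings_match_svd_oracle(self, rng):
        """Loadings agree with an SVD of the z-scored matrix up to sign."""
        X = rng.standard_normal((50, 3)) @ rng.standard_normal((3, 3))
        res = comp.pca(pd.DataFrame(X, columns=list("abc")), cumulative_target=1.01)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        _, s, Vt = np.linalg.svd(Z / np.sqrt(len(X) - 1), full_matrices=False)
        expected = Vt.T * s
        for k in range(res.loadings.shape[1]):
            col, exp = res.loadings[:, k], expected[:, k]
            assert np.allclose(col, exp, atol=1e-8) or np.allclose(col, -exp, atol=1e-8)

    def test_eigenvalues_sum_to_p_and_cumulative_structure(self, rng):
        X = rng.standard_normal((60, 4))
        res = comp.pca(pd.DataFrame(X))
        assert res.eigenvalues.sum() == pytest.approx(4.0, abs=1e-9)
        assert res.cumulative_pct[-1] == pytest.approx(100.0, abs=1e-9)
        assert (np.diff(res.cumulative_pct) >= -1e-12).all()
        np.testing.assert_allclose(
            res.cumulative_pct, np.cumsum(res.pct_variance), atol=1e-12
        )

    def test_perfectly_correlated_pair(self, rng):
        x = rng.standard_normal(40)
        res = comp.pca(pd.DataFrame({"a": x, "b": 2 * x + 1}))
        assert res.eigenvalues[0] == pytest.approx(2.0, abs=1e-9)
        assert res.pct_variance[0] == pytest.approx(100.0, abs=1e-9)

    def test_varimax_preserves_communalities(self, rng):
        t = rng.standard_normal(120)
        u = rng.standard_normal(120)
        X = np.column_stack(
            [t + 0.3 * rng.standard_normal(120) for _ in range(2)]
            + [u + 0.3 * rng.standard_normal(120) for _ in range(2)]
        )
        res = comp.pca(pd.DataFrame(X), cumulative_target=0.9)
        assert res.n_retained >= 2
        rotated_comm = (res.rotated_loadings**2).sum(axis=1)
        np.testing.assert_allclose(rotated_comm, res.communalities, atol=1e-9)
        assert ((res.communalities >= -1e-9) & (res.communalities <= 1 + 1e-9)).all()

    def test_needs_more_rows_than_columns(self, rng):
        with pytest.raises(ValueError):
            comp.pca(pd.DataFrame(rng.standard_normal((3, 4))))


class TestCompositeWeights:
    def test_single_component_single_dominant_indicator(self):
        w, _, _ = comp.combine_score_coefficients(np.array([[1.0]]), np.array([2.0]))
        assert w[0] == pytest.approx(1.0)

    def test_two_identical_indicators_share_weight(self, rng):
        x = rng.standard_normal(80)
        y = rng.standard_normal(80)
        res = comp.pca(
            pd.DataFrame({"a": x, "b": x + 1e-9 * rng.standard_normal(80), "c": y})
        )
        weights, _ = comp.composite_weights(res)
        assert weights["a"] == pytest.approx(weights["b"], abs=1e-4)

    def test_negative_combined_coefficient_flagged(self):
        S = np.array([[1.0], [-0.2]])
        w, combined, flags = comp.combine_score_coefficients(S, np.array([1.0]))
        assert flags and combined[1] < 0
        assert w.sum() == pytest.approx(1.0)


class TestSelectBestIndex:
    def test_identical_to_lai_passes_gate(self, rng):
        n = 300
        lai = rng.uniform(0, 6, n)
        npp = 0.8 * lai + rng.normal(0, 0.5, n)
        cands = {"good": lai.copy(), "noise": rng.standard_normal(n)}
        chosen, report = comp.select_best_index(cands, npp, lai)
        assert bool(report.loc["good", "passes"])
        assert report.loc["good", "r_lai"] == pytest.approx(1.0)

    def test_shared_latent_factor_candidate_selected(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 400
            f = rng.standard_normal(n)
            npp = f + 0.4 * rng.standard_normal(n)
            lai = f + 0.4 * rng.standard_normal(n)
            cands = {
                "arvi_like": f + 0.4 * rng.standard_normal(n),
                "weak1": 0.3 * f + rng.standard_normal(n),
                "weak2": 0.2 * f + rng.standard_normal(n),
            }
            chosen, _ = comp.select_best_index(cands, npp, lai)
            hits += chosen == "arvi_like"
        assert hits >= 9

    def test_kmo_gate_excludes_low_adequacy(self, rng):
        n = 500
        npp = rng.standard_normal(n)
        lai = rng.standard_normal(n)
        cands = {"a": rng.standard_normal(n), "b": rng.standard_normal(n)}
        _, report = comp.select_best_index(cands, npp, lai, kmo_gate=0.5)
        assert not report["passes"].any()


class TestVegRaster:
    def test_constant_indicators_give_constant_half(self, open_geometry):
        grids = {
            k: RasterGrid(np.full(open_geometry.shape, v), open_geometry)
            for k, v in (("NPP", 3.0), ("LAI", 2.0), ("ARVI", 0.5))
        }
        weights = pd.Series([0.372, 0.370, 0.258], index=["NPP", "LAI", "ARVI"])
        out = comp.veg_raster(weights, grids)
        np.testing.assert_allclose(out.values, 0.5)

    def test_degenerate_weights_reproduce_rescaled_indicator(self, open_geometry, rng):
        grids = {
            "NPP": RasterGrid(rng.uniform(0, 100, open_geometry.shape), open_geometry),
            "LAI": RasterGrid(rng.uniform(0, 6, open_geometry.shape), open_geometry),
        }
        weights = pd.Series([1.0, 0.0], index=["NPP", "LAI"])
        out = comp.veg_raster(weights, grids)
        np.testing.assert_allclose(out.data, grids["NPP"].rescaled().data, atol=1e-12)

    def test_weights_summing_to_one_keep_unit_range(self, open_geometry, rng):
        grids = {
            k: RasterGrid(rng.uniform(-5, 5, open_geometry.shape), open_geometry)
            for k in ("a", "b", "c")
        }
        weights = pd.Series([0.372, 0.370, 0.258], index=["a", "b", "c"])
        out = comp.veg_raster(weights, grids)
        assert out.values.min() >= -1e-12 and out.values.max() <= 1 + 1e-12

    def test_missing_indicator_grid_is_an_error(self, open_geometry):
        weights = pd.Series([0.5, 0.5], index=["a", "b"])
        grids = {"a": RasterGrid(np.zeros(open_geometry.shape), open_geometry)}
        with pytest.raises(KeyError, match="b"):
            comp.veg_raster(weights, grids)
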