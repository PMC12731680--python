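"""Selector primitives against closed forms and independent oracles."""

import numpy as np
import pytest

from crackspec.band_selection import (BandSubset, CarsConfig, RfConfig,
                                      apply_subset, cars_select, cars_weights,
                                      dimensionality_reduction_pct, plsr_fit,
                                      random_frog_select, rf_acceptance,
                                      rmsecv, spa_project, spa_select)
from crackspec.core import WavelengthGrid
from crackspec.errors import ParameterError
from crackspec.preprocess import SpectraMatrix
from crackspec.synthetic_data import planted_band_spectra


def _matrix(X, y):
    grid = WavelengthGrid(np.linspace(1000, 2500, X.shape[1]))
    return SpectraMatrix(X=X, y=y, band_grid=grid)


class TestCarsWeights:
    def test_worked_example(self):
        np.testing.assert_allclose(cars_weights(np.array([1.0, -1.0, 2.0])),
                                   [0.25, 0.25, 0.5])

    def test_single_nonzero_is_one_hot(self):
        np.testing.assert_allclose(cars_weights(np.array([0.0, 0.0, -3.0])),
                                   [0.0, 0.0, 1.0])

    def test_weights_always_normalized(self, rng):
        for _ in range(20):
            beta = rng.standard_normal(rng.integers(2, 30))
            w = cars_weights(beta)
            assert w.min() >= 0
            assert np.isclose(w.sum(), 1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ParameterError):
            cars_weights(np.zeros(5))


class TestPlsrFit:
    def test_informative_column_dominates(self, rng):
        X = rng.standard_normal((80, 10))
        y = 3.0 * X[:, 4]
        beta = plsr_fit(X, y, n_latent=1)
        assert np.argmax(np.abs(beta)) == 4
        # OLS on the single informative column recovers slope 3
        ols = np.linalg.lstsq(X[:, [4]], y, rcond=None)[0][0]
        assert np.isclose(ols, 3.0)
        assert np.abs(beta[4]) > 0.5 * np.abs(ols)

    def test_constant_response_gives_zero_beta(self, rng):
        beta = plsr_fit(rng.standard_normal((20, 6)), np.ones(20))
        np.testing.assert_array_equal(beta, 0)

    def test_full_rank_matches_ols_predictions(self, rng):
        X = rng.standard_normal((40, 5))
        y = X @ rng.standard_normal(5) + 0.01 * rng.standard_normal(40)
        beta = plsr_fit(X, y, n_latent=5)
        Xc = X - X.mean(axis=0)
        beta_ols = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        np.testing.assert_allclose(Xc @ beta, Xc @ beta_ols, atol=1e-6)


class TestSpaProject:
    def test_orthogonal_vector_unchanged(self):
        Xs = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        xj = np.array([0.0, 0.0, 2.0])
        np.testing.assert_allclose(spa_project(xj, Xs), xj)

    def test_in_span_vector_annihilated(self):
        Xs = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        xj = np.array([3.0, -2.0, 0.0])
        np.testing.assert_allclose(spa_project(xj, Xs), 0, atol=1e-12)

    def test_matches_gram_schmidt_oracle(self, rng):
        Xs = rng.standard_normal((30, 4))
        xj = rng.standard_normal(30)
        # independent oracle: sequential Gram-Schmidt removal
        residual = xj.copy()
        basis = []
        for col in Xs.T:
            v = col.copy()
            for b in basis:
                v -= (v @ b) * b
            basis.append(v / np.linalg.norm(v))
        for b in basis:
            residual -= (residual @ b) * b
        np.testing.assert_allclose(spa_project(xj, Xs), residual, atol=1e-8)
        # residual is orthogonal to every selected column
        assert np.allclose(Xs.T @ spa_project(xj, Xs), 0, atol=1e-8)


class TestRfAcceptance:
    def test_improvement_always_accepted(self):
        assert rf_acceptance(1.0, 0.5, 0.1) == 1.0

    def test_tie_accepted(self):
        assert rf_acceptance(0.7, 0.7, 0.3) == 1.0

    def test_worked_value(self):
        assert np.isclose(rf_acceptance(1.0, 1.5, 0.5), np.exp(-1.0))

    def test_greedy_limit_at_tiny_temperature(self):
        assert rf_acceptance(1.0, 1.001, 1e-9) == 0.0

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ParameterError):
            rf_acceptance(1.0, 0.5, 0.0)


class TestRmsecv:
    def test_noiseless_linear_response_near_zero(self, rng):
        X = rng.standard_normal((60, 8))
        y = X[:, 2] - 0.5 * X[:, 5]
        M = _matrix(X, y)
        assert rmsecv(M, [2, 5], n_latent=2, seed=0) < 1e-6

    def test_pure_noise_rmse_near_std(self, rng):
        vals = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = r.standard_normal((100, 6))
            y = r.standard_normal(100)
            vals.append(rmsecv(_matrix(X, y), [0, 1, 2], n_latent=2,
                               seed=seed) / y.std())
        assert 0.8 < np.mean(vals) < 1.3

    def test_noise_bands_do_not_help(self, rng):
        X = rng.standard_normal((100, 10))
        y = X[:, 0] + 0.1 * rng.standard_normal(100)
        M = _matrix(X, y)
        informative = rmsecv(M, [0], n_latent=1, seed=3)
        with_noise = rmsecv(M, [0, 4, 7, 9], n_latent=1, seed=3)
        assert with_noise >= informative - 0.05

    def test_deterministic_under_seed(self, rng):
        M, _ = planted_band_spectra(n_samples=50, n_bands=10, seed=0)
        assert rmsecv(M, [0, 3], seed=5) == rmsecv(M, [0, 3], seed=5)


class TestCarsSelect:
    def test_degenerate_single_band(self, rng):
        X = rng.standard_normal((30, 1))
        y = (X[:, 0] > 0).astype(int)
        sub = cars_select(_matrix(X, y), CarsConfig(n_iterations=5, seed=0))
        assert sub.indices.tolist() == [0]
        assert sub.rmsecv_trace is not None and len(sub.rmsecv_trace) >= 1

    def test_argmin_contract_and_reproducibility(self):
        M, _ = planted_band_spectra(n_samples=80, n_bands=20, seed=2)
        cfg = CarsConfig(n_iterations=15, mc_draws=5, seed=7)
        a = cars_select(M, cfg)
        b = cars_select(M, cfg)
        np.testing.assert_array_equal(a.indices, b.indices)
        np.testing.assert_allclose(a.rmsecv_trace, b.rmsecv_trace)
        assert len(a.rmsecv_trace) <= 15

    def test_planted_bands_recovered(self):
        M, planted = planted_band_spectra(seed=11)
        sub = cars_select(M, CarsConfig(mc_draws=10, seed=11))
        assert set(planted) <= set(sub.indices)


class TestSpaSelect:
    def test_starts_at_largest_norm_column(self):
        X = np.zeros((5, 3))
        X[0, 0], X[1, 1], X[2, 2] = 2.0, 3.0, 1.0  # orthogonal, norms 2,3,1
        y = np.array([0, 1, 0, 1, 0])
        sub = spa_select(_matrix(X, y), max_bands=3, n_latent=1,
                         mc_draws=3, seed=0)
        assert sub.rmse_by_count is not None
        # the chain must begin at column 1 (norm 3)
        assert 1 in sub.indices

    def test_duplicate_column_never_selected_twice(self, rng):
        X = rng.standard_normal((40, 6))
        X[:, 3] = X[:, 0]  # exact duplicate
        y = (X[:, 0] > 0).astype(int)
        sub = spa_select(_matrix(X, y), max_bands=6, mc_draws=3, seed=0)
        assert not {0, 3} <= set(sub.indices)

    def test_planted_bands_recovered(self):
        M, planted = planted_band_spectra(seed=21)
        sub = spa_select(M, max_bands=20, mc_draws=10, seed=21)
        assert set(planted) <= set(sub.indices)

    def test_low_collinearity_versus_random_subsets(self, rng):
        M, _ = planted_band_spectra(seed=5)

        def mean_abs_corr(idx):
            c = np.corrcoef(M.X[:, idx].T)
            off = c[~np.eye(len(idx), dtype=bool)]
            return np.abs(off).mean()

        sub = spa_select(M, max_bands=10, mc_draws=5, seed=5)
        if sub.n_bands < 2:
            pytest.skip("subset too small to measure collinearity")
        spa_corr = mean_abs_corr(sub.indices)
        random_corrs = [
            mean_abs_corr(rng.choice(M.n_bands, size=sub.n_bands,
                                     replace=False))
            for _ in range(30)
        ]
        assert spa_corr < np.mean(random_corrs)


class TestRandomFrog:
    def test_probability_bounds_and_reproducibility(self):
        M, _ = planted_band_spectra(n_samples=80, n_bands=15, seed=3)
        cfg = RfConfig(n_iterations=60, mc_draws=3, seed=3)
        a = random_frog_select(M, cfg)
        b = random_frog_select(M, cfg)
        assert np.all((a.selection_probability >= 0)
                      & (a.selection_probability <= 1))
        np.testing.assert_array_equal(a.indices, b.indices)

    def test_planted_bands_exceed_threshold(self):
        M, planted = planted_band_spectra(seed=31)
        sub = random_frog_select(M, RfConfig(seed=31))
        assert np.all(sub.selection_probability[planted] > 0.2)


class TestApplySubset:
    def test_identity_subset(self, small_cube):
        sub = BandSubset(indices=np.arange(small_cube.bands))
        out = apply_subset(small_cube, sub)
        np.testing.assert_array_equal(out.data, small_cube.data)

    def test_reduction_to_requested_bands(self, small_cube):
        sub = BandSubset(indices=[1, 4, 7])
        out = apply_subset(small_cube, sub)
        assert out.bands == 3
        np.testing.assert_allclose(
            out.grid.centers_nm, small_cube.grid.centers_nm[[1, 4, 7]])

    def test_out_of_range_rejected(self, small_cube):
        with pytest.raises(ParameterError):
            apply_subset(small_cube, BandSubset(indices=[small_cube.bands]))


def test_dimensionality_reduction_headline():
    assert dimensionality_reduction_pct(15, 273) == pytest.approx(94.505, abs=0.01)
    assert dimensionality_reduction_pct(15, 273) >= 90.0


def test_band_subset_json_round_trip(tmp_path):
    sub = BandSubset(indices=[3, 1, 7], method="SPA",
                     wavelengths_nm=np.array([1100.0, 1200.0, 1400.0]),
                     rmse_by_count=np.array([0.4, 0.3, 0.35]))
    back = BandSubset.from_json(sub.to_json(tmp_path / "s.json"))
    np.testing.assert_array_equal(back.indices, [1, 3, 7])
    assert back.method == "SPA"
    np.testing.assert_allclose(back.rmse_by_count, [0.4, 0.3, 0.35])
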