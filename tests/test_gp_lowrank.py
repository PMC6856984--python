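"""Low-rank Matern GP with the additive inverse-input kernel."""

import numpy as np
import pytest

import lvemulate as lv
from lvemulate.gp_lowrank import LowRankGPEmulator, matern32_matrix


class TestMaternKernel:
    def test_zero_distance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert lv.matern32_kernel(x, x, scale=1.3, length=2.0) == pytest.approx(1.3**2)

    def test_closed_form_at_r_equals_length(self):
        x = np.zeros(4)
        y = np.array([2.0, 0.0, 0.0, 0.0])
        expected = (1.0 + np.sqrt(3.0)) * np.exp(-np.sqrt(3.0))
        assert lv.matern32_kernel(x, y, length=2.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.483358, abs=1e-6)

    def test_monotone_decreasing_in_distance(self):
        x = np.zeros(4)
        vals = [
            lv.matern32_kernel(x, np.array([r, 0, 0, 0]), length=1.5)
            for r in np.linspace(0.0, 5.0, 40)
        ]
        assert np.all(np.diff(vals) < 0)


class TestDefaultLengthScale:
    def test_two_point_distance(self):
        X = np.array([[0.1] * 4, [5.0] * 4])
        assert lv.default_length_scale(X) == pytest.approx(4.9 * 2.0)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="degenerate|coincide"):
            lv.default_length_scale(np.ones((5, 4)))

    def test_matches_brute_force_pairwise_max(self, rng):
        X = rng.uniform(0.1, 5.0, (40, 4))
        best = max(
            np.linalg.norm(X[i] - X[j]) for i in range(40) for j in range(i + 1, 40)
        )
        assert lv.default_length_scale(X) == pytest.approx(best, rel=1e-12)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            lv.default_length_scale(np.ones((1, 4)))


class TestTruncatedEigendecomposition:
    def test_identity_exact(self):
        U, d = lv.truncated_eigendecomposition(np.eye(5), 5)
        np.testing.assert_allclose(d, np.ones(5))
        np.testing.assert_allclose(U @ np.diag(d) @ U.T, np.eye(5), atol=1e-12)

    def test_rank_one_exact(self, rng):
        v = rng.standard_normal(8)
        C = np.outer(v, v)
        U, d = lv.truncated_eigendecomposition(C, 1)
        np.testing.assert_allclose(U @ np.diag(d) @ U.T, C, atol=1e-10)

    def test_matches_dense_oracle_on_random_psd(self, rng):
        A = rng.standard_normal((50, 50))
        C = A @ A.T
        U, d = lv.truncated_eigendecomposition(C, 10)
        oracle = np.sort(np.linalg.eigvalsh(C))[::-1][:10]
        np.testing.assert_allclose(d, oracle, atol=1e-8 * oracle[0])
        # eigenpair residuals and orthonormality
        for i in range(10):
            assert np.linalg.norm(C @ U[:, i] - d[i] * U[:, i]) <= 1e-6 * abs(d[i])
        np.testing.assert_allclose(U.T @ U, np.eye(10), atol=1e-10)

    def test_non_symmetric_rejected(self, rng):
        with pytest.raises(ValueError, match="symmetric"):
            lv.truncated_eigendecomposition(rng.standard_normal((6, 6)), 2)

    def test_truncation_error_monotone_in_k(self, rng):
        A = rng.standard_normal((30, 30))
        C = A @ A.T
        errs = []
        for k in (2, 5, 10, 20, 30):
            U, d = lv.truncated_eigendecomposition(C, k)
            errs.append(np.linalg.norm(C - U @ np.diag(d) @ U.T))
        assert all(a >= b - 1e-10 for a, b in zip(errs, errs[1:]))


def smooth_target(X):
    return np.sin(X[:, 0]) + X[:, 1] ** 0.5 + 0.3 * X[:, 2] * X[:, 3] / 5.0


class TestFitPredict:
    def test_self_fit_r2(self, rng):
        X = rng.uniform(0.1, 5.0, (200, 4))
        y = smooth_target(X)
        fit = lv.fit_lowrank(X, y, nr=200, k=200, seed=0)
        preds = np.array([lv.predict_lowrank(fit, x)[0] for x in X])
        ss_res = np.sum((preds - y) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert 1.0 - ss_res / ss_tot > 0.99

    def test_same_seed_same_subsample_and_fit(self, rng):
        X = rng.uniform(0.1, 5.0, (120, 4))
        y = smooth_target(X)
        a = lv.fit_lowrank(X, y, nr=60, k=30, seed=5)
        b = lv.fit_lowrank(X, y, nr=60, k=30, seed=5)
        np.testing.assert_array_equal(a.subsample_indices, b.subsample_indices)
        assert a.output_scale == b.output_scale
        assert lv.predict_lowrank(a, np.full(4, 2.0)) == lv.predict_lowrank(b, np.full(4, 2.0))

    def test_full_rank_matches_exact_gp_oracle(self, rng):
        """nr = N, k = N reproduces exact GP regression with the summed kernel."""
        X = rng.uniform(0.1, 5.0, (40, 4))
        y = smooth_target(X)
        fit = lv.fit_lowrank(X, y, nr=40, k=40, seed=0)
        T = 1.0 / X
        K0 = matern32_matrix(X, X, fit.length_theta) + matern32_matrix(T, T, fit.length_tau)
        C = fit.output_scale**2 * K0 + fit.noise_sd**2 * np.eye(40)
        star = rng.uniform(0.2, 4.8, 4)
        k0 = (
            matern32_matrix(star[None, :], X, fit.length_theta)
            + matern32_matrix((1.0 / star)[None, :], T, fit.length_tau)
        )[0]
        kstar = fit.output_scale**2 * k0
        mean_oracle = fit.beta + kstar @ np.linalg.solve(C, y - fit.beta)
        var_oracle = 2.0 * fit.output_scale**2 - kstar @ np.linalg.solve(C, kstar)
        mean, var = lv.predict_lowrank(fit, star)
        assert mean == pytest.approx(mean_oracle, abs=1e-6)
        assert var == pytest.approx(max(var_oracle, 0.0), abs=1e-6)

    def test_interpolates_retained_points(self, rng):
        X = rng.uniform(0.1, 5.0, (150, 4))
        y = smooth_target(X)
        fit = lv.fit_lowrank(X, y, nr=150, k=150, seed=0)
        rng_idx = fit.subsample_indices[::25]
        rng_range = y.max() - y.min()
        for i in rng_idx:
            mean, _ = lv.predict_lowrank(fit, X[i])
            assert abs(mean - y[i]) < 0.01 * rng_range

    def test_prediction_continuity(self, rng):
        X = rng.uniform(0.1, 5.0, (80, 4))
        y = smooth_target(X)
        fit = lv.fit_lowrank(X, y, nr=80, k=40, seed=0)
        x0 = np.full(4, 2.0)
        m0, _ = lv.predict_lowrank(fit, x0)
        gaps = []
        for delta in (1e-2, 1e-4, 1e-6):
            m1, _ = lv.predict_lowrank(fit, x0 + delta)
            gaps.append(abs(m1 - m0))
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 1e-5

    def test_k_exceeding_nr_rejected(self, rng):
        X = rng.uniform(0.1, 5.0, (30, 4))
        with pytest.raises(ValueError, match="exceeds"):
            lv.fit_lowrank(X, smooth_target(X), nr=20, k=25)

    def test_rmse_improves_with_rank(self):
        """Test RMSE on the toy simulator decreases (or plateaus) as k grows."""
        train, test = lv.generate_dataset(500, 30)
        y = train.outputs[:, 0]
        rmses = []
        for k in (50, 150, 500):
            fit = lv.fit_lowrank(train.design, y, nr=500, k=k, seed=0)
            preds = np.array([lv.predict_lowrank(fit, x)[0] for x in test.design])
            rmses.append(float(np.sqrt(np.mean((preds - test.outputs[:, 0]) ** 2))))
        assert rmses[-1] <= rmses[0] * 1.05


class TestEmulator:
    def test_multi_column_consistent_with_single_fits(self, small_dataset):
        train, test = small_dataset
        em = LowRankGPEmulator(train.design, train.outputs[:, :3], nr=train.n, k=128, seed=2)
        means, variances = em.predict(test.design[0])
        for j in range(3):
            fit = lv.fit_lowrank(train.design, train.outputs[:, j], nr=train.n, k=128, seed=2)
            m, v = lv.predict_lowrank(fit, test.design[0])
            assert means[j] == pytest.approx(m, rel=1e-8, abs=1e-10)
            assert variances[j] == pytest.approx(v, rel=1e-6, abs=1e-10)

    def test_refit_target_reuses_basis(self, small_dataset):
        train, _ = small_dataset
        em = LowRankGPEmulator(train.design, train.outputs[:, 0], nr=train.n, k=64, seed=0)
        U_before = em.U
        em.refit_target(train.outputs[:, 1])
        assert em.U is U_before
        fresh = LowRankGPEmulator(train.design, train.outputs[:, 1], nr=train.n, k=64, seed=0)
        x = np.full(4, 1.7)
        assert em.predict(x)[0] == pytest.approx(fresh.predict(x)[0], rel=1e-10)

    def test_predict_mean_fast_path_matches_predict(self, small_dataset):
        train, test = small_dataset
        em = LowRankGPEmulator(train.design, train.outputs[:, :5], nr=128, k=64, seed=1)
        means_full, _ = em.predict(test.design[0])
        np.testing.assert_allclose(em.predict_mean(test.design[0]), means_full, rtol=1e-12)
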