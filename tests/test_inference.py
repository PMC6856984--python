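"""Emulation strategies, multistart optimization, Hessian uncertainty."""

import numpy as np
import pytest

import lvemulate as lv
from lvemulate.inference import OptimConfig, _chained_descent, hessian_uncertainty
from lvemulate.losses import LossSpec


class TestOutputEmulatorBundle:
    def test_bundle_holds_25_output_emulators(self, small_dataset):
        train, _ = small_dataset
        bundle = lv.build_output_emulator(train, "local_gp", gp_options={"K": 40})
        assert bundle.n_outputs == 25
        assert bundle.predict_outputs(train.design[0]).shape == (25,)

    def test_prediction_close_to_training_row(self, small_dataset):
        train, _ = small_dataset
        bundle = lv.build_output_emulator(train, "local_gp", gp_options={"K": 40})
        pred = bundle.predict_outputs(train.design[10])
        rel = np.abs(pred - train.outputs[10]) / np.maximum(np.abs(train.outputs[10]), 1e-12)
        assert rel.max() < 0.01

    def test_unknown_interpolator_rejected(self, small_dataset):
        train, _ = small_dataset
        with pytest.raises(ValueError, match="interpolator"):
            lv.build_output_emulator(train, "spline")


class TestSurrogateOutputLoss:
    def test_zero_when_observation_equals_prediction(self, small_dataset):
        train, _ = small_dataset
        bundle = lv.build_output_emulator(train, "lowrank_gp", gp_options={"nr": 128, "k": 64})
        theta = np.full(4, 2.0)
        y0 = bundle.predict_outputs(theta)
        assert lv.surrogate_output_loss(theta, bundle, y0) == pytest.approx(0.0, abs=1e-20)

    def test_composition_with_euclidean_loss(self, small_dataset):
        train, test = small_dataset
        bundle = lv.build_output_emulator(train, "lowrank_gp", gp_options={"nr": 128, "k": 64})
        theta = np.full(4, 1.5)
        y0 = test.outputs[0]
        expected = lv.euclidean_loss(bundle.predict_outputs(theta), y0, bundle.loss_spec.sigma)
        assert lv.surrogate_output_loss(theta, bundle, y0) == pytest.approx(expected, rel=1e-12)

    def test_finite_over_hyperbox_scan(self, small_dataset):
        train, test = small_dataset
        bundle = lv.build_output_emulator(train, "lowrank_gp", gp_options={"nr": 128, "k": 64})
        y0 = test.outputs[0]
        grid = np.linspace(0.1, 5.0, 4)
        for t1 in grid:
            for t2 in grid:
                val = lv.surrogate_output_loss(np.array([t1, t2, 2.0, 3.0]), bundle, y0)
                assert np.isfinite(val)

    def test_strategy_mismatch(self, small_dataset):
        train, test = small_dataset
        bundle = lv.build_loss_emulator(
            train, test.outputs[0], interpolator="lowrank_gp", gp_options={"nr": 64, "k": 32}
        )
        with pytest.raises(ValueError, match="output-strategy"):
            lv.surrogate_output_loss(np.full(4, 1.0), bundle, test.outputs[0])


class TestLossEmulator:
    def test_training_losses_match_definition(self, small_dataset):
        train, test = small_dataset
        y0 = test.outputs[1]
        spec = LossSpec("euclidean", sigma=1.0)
        expected = 0.5 * np.sum((train.outputs - y0) ** 2, axis=1)
        np.testing.assert_allclose(spec.batch(train.outputs, y0), expected, rtol=1e-12)

    def test_self_fit_quality(self, small_dataset):
        """Training-point predictions track the true losses (Spearman > 0.95)."""
        from scipy.stats import spearmanr

        train, test = small_dataset
        y0 = test.outputs[0]
        bundle = lv.build_loss_emulator(
            train, y0, interpolator="lowrank_gp", gp_options={"nr": train.n}
        )
        truth = bundle.loss_spec.batch(train.outputs, y0)
        preds = np.array([bundle.emulator.predict(x)[0] for x in train.design[::4]])
        rho = spearmanr(preds, truth[::4]).statistic
        assert rho > 0.95

    def test_observation_equal_to_training_output(self, small_dataset):
        train, _ = small_dataset
        k = 33
        y0 = train.outputs[k]
        spec = LossSpec("euclidean")
        losses = spec.batch(train.outputs, y0)
        assert np.argmin(losses) == k and losses[k] == 0.0

    def test_wrong_observation_length(self, small_dataset):
        train, _ = small_dataset
        with pytest.raises(ValueError, match="observation length"):
            lv.build_loss_emulator(train, np.zeros(7), interpolator="lowrank_gp")


class TestMultistartMinimize:
    def test_convex_quadratic(self):
        center = np.array([2.0, 3.0, 1.0, 4.0])

        def objective(x):
            return float(np.sum((x - center) ** 2))

        theta, val, diag = lv.multistart_minimize(objective, OptimConfig(n_starts=8, seed=0))
        np.testing.assert_allclose(theta, center, atol=1e-6)
        assert val < 1e-10

    def test_two_well_objective_finds_global(self):
        """Sum of two inverted Gaussians: the deeper one must be found."""
        deep = np.array([1.0, 1.0, 1.0, 1.0])
        shallow = np.array([4.0, 4.0, 4.0, 4.0])

        def objective(x):
            return float(
                2.0
                - 1.5 * np.exp(-np.sum((x - deep) ** 2) / 0.5)
                - 1.0 * np.exp(-np.sum((x - shallow) ** 2) / 0.5)
            )

        theta, _, _ = lv.multistart_minimize(objective, OptimConfig(n_starts=50, seed=3))
        np.testing.assert_allclose(theta, deep, atol=1e-4)

    def test_result_always_within_bounds(self):
        def objective(x):
            return float(np.sum((x - 10.0) ** 2))  # pulls outside the box

        theta, _, _ = lv.multistart_minimize(objective, OptimConfig(n_starts=5, seed=1))
        assert np.all(theta >= 0.1) and np.all(theta <= 5.0)

    def test_extra_starts_are_used(self):
        center = np.array([0.11, 4.9, 0.11, 4.9])

        def objective(x):
            d2 = np.sum((x - center) ** 2)
            return float(d2 if d2 < 0.01 else 1.0)  # flat except a needle

        theta, val, _ = lv.multistart_minimize(
            objective, OptimConfig(n_starts=4, seed=0), extra_starts=[center + 1e-3]
        )
        assert val < 1e-4


class TestHessianUncertainty:
    def test_quadratic_known_curvature(self):
        A = np.array(
            [
                [4.0, 1.0, 0.0, 0.0],
                [1.0, 3.0, 0.5, 0.0],
                [0.0, 0.5, 2.0, 0.2],
                [0.0, 0.0, 0.2, 5.0],
            ]
        )
        theta_hat = np.array([2.0, 2.5, 3.0, 1.5])

        def objective(x):
            d = x - theta_hat
            return 0.5 * float(d @ A @ d)

        cov, samples, bands = hessian_uncertainty(objective, theta_hat, n_samples=500, seed=0)
        np.testing.assert_allclose(cov, np.linalg.inv(A), rtol=1e-4)

    def test_sample_mean_converges_to_estimate(self):
        A = np.diag([50.0, 60.0, 70.0, 80.0])
        theta_hat = np.array([2.5, 2.5, 2.5, 2.5])

        def objective(x):
            d = x - theta_hat
            return 0.5 * float(d @ A @ d)

        n = 4000
        cov, samples, _ = hessian_uncertainty(objective, theta_hat, n_samples=n, seed=1)
        sd_max = np.sqrt(np.diag(cov)).max()
        assert np.linalg.norm(samples.mean(axis=0) - theta_hat) < 3.0 * sd_max / np.sqrt(n) * 2.0

    def test_bands_collapse_at_unit_stretch_and_contain_point_curve(self):
        A = np.diag([30.0, 30.0, 30.0, 30.0])
        theta_hat = np.array([1.0, 1.0, 1.0, 1.0])

        def objective(x):
            d = x - theta_hat
            return 0.5 * float(d @ A @ d)

        _, _, (fib, sheet) = hessian_uncertainty(objective, theta_hat, n_samples=200, seed=2)
        for band in (fib, sheet):
            assert band.stresses[0] == 0.0
            assert band.lower[0] == 0.0 and band.upper[0] == 0.0
            assert np.all(band.lower <= band.stresses + 1e-12)
            assert np.all(band.upper >= band.stresses - 1e-12)

    def test_samples_respect_bounds(self):
        A = np.diag([0.5, 0.5, 0.5, 0.5])  # huge covariance, heavy truncation
        theta_hat = np.array([0.3, 4.8, 2.0, 2.0])

        def objective(x):
            d = x - theta_hat
            return 0.5 * float(d @ A @ d)

        _, samples, _ = hessian_uncertainty(objective, theta_hat, n_samples=300, seed=3)
        assert np.all(samples >= 0.1) and np.all(samples <= 5.0)


class TestEstimateParameters:
    def test_wrong_observation_length(self, small_dataset):
        train, _ = small_dataset
        with pytest.raises(ValueError, match="observation length"):
            lv.estimate_parameters(np.zeros(10), train, uq=False)

    def test_deterministic_given_seed(self, small_dataset):
        train, test = small_dataset
        kwargs = dict(
            strategy="loss",
            interpolator="lowrank_gp",
            optim_config=OptimConfig(n_starts=6, seed=11),
            uq=False,
            gp_options={"nr": 128, "k": 64},
        )
        a = lv.estimate_parameters(test.outputs[0], train, **kwargs)
        b = lv.estimate_parameters(test.outputs[0], train, **kwargs)
        np.testing.assert_array_equal(a.theta_hat, b.theta_hat)

    def test_output_strategy_recovers_parameters_coarsely(self, small_dataset):
        """Even 256 training points localize the truth on the easy directions."""
        train, test = small_dataset
        res = lv.estimate_parameters(
            test.outputs[0],
            train,
            optim_config=OptimConfig(n_starts=8, seed=5),
            uq=False,
            gp_options={"K": 60},
        )
        assert res.loss_min < 1e-2
        assert np.all(res.theta_hat >= 0.1) and np.all(res.theta_hat <= 5.0)

    def test_uq_attached_when_requested(self, small_dataset):
        train, test = small_dataset
        res = lv.estimate_parameters(
            test.outputs[1],
            train,
            strategy="loss",
            interpolator="lowrank_gp",
            optim_config=OptimConfig(n_starts=4, seed=2),
            uq=True,
            n_samples=100,
            gp_options={"nr": 128, "k": 64},
        )
        assert res.covariance.shape == (4, 4)
        assert res.mvn_samples.shape == (100, 4)
        assert res.fibre_band is not None and res.sheet_band is not None
        w = np.linalg.eigvalsh(res.covariance)
        assert np.all(w >= -1e-12)


def test_chained_descent_handles_flat_restart():
    def objective(x):
        return float(np.sum(x**2))

    res = _chained_descent(objective, np.full(4, 3.0), (0.1, 5.0), 4, 100, 1e-8)
    np.testing.assert_allclose(res.x, np.full(4, 0.1), atol=1e-8)
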