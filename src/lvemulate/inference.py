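"""Surrogate-based parameter estimation with uncertainty quantification.

Two emulation strategies connect the precomputed simulations to a new
observation y0 (24 strains + volume):

- *output emulation*: one scalar emulator per simulator output, fitted before
  y0 arrives; the surrogate loss compares the emulated output vector with y0;
- *loss emulation*: the chosen loss is evaluated between every training
  output and y0, and a single scalar emulator of that loss surface is fitted
  (only possible once y0 is known); the minimized quantity is the emulator's
  predictive mean.

Either strategy's objective is minimized over the [0.1, 5]^4 hyperbox by a
multistart scheme: Sobol-scattered starting points ranked by objective value,
bounded quasi-Newton descent from each, skipping starts that fall inside the
basin of attraction (sphere of radius ||start - minimum||) of a previously
found minimum.  Uncertainty is quantified by the inverse of the numerically
estimated Hessian at the minimum, used as the covariance of a multivariate
normal around the estimate; samples (truncated to the hyperbox) induce 95%
bands on the fibre/sheet stretch-stress curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Tuple

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from .gp_local import LocalGPEmulator
from .gp_lowrank import LowRankGPEmulator
from .ho import (
    THETA_LOWER,
    THETA_UPPER,
    ReferenceValues,
    StretchStressCurve,
    stretch_stress_curve,
)
from .losses import LossSpec
from .simulator import Dataset

__all__ = [
    "OptimConfig",
    "EmulatorBundle",
    "InferenceResult",
    "build_output_emulator",
    "surrogate_output_loss",
    "build_loss_emulator",
    "multistart_minimize",
    "hessian_uncertainty",
    "estimate_parameters",
]

Strategy = Literal["output", "loss"]
Interpolator = Literal["local_gp", "lowrank_gp"]

DEFAULT_LOWRANK_K_OUTPUT = 2000
DEFAULT_LOWRANK_K_LOSS = 1000


@dataclass(frozen=True)
class OptimConfig:
    """Multistart optimizer settings over the design hyperbox."""

    bounds: Tuple[float, float] = (THETA_LOWER, THETA_UPPER)
    n_starts: int = 50
    maxiter: int = 100
    tol: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if not self.bounds[0] < self.bounds[1]:
            raise ValueError("invalid bounds")


@dataclass
class EmulatorBundle:
    """A fitted emulation strategy ready to be queried by the optimizer."""

    strategy: Strategy
    interpolator: Interpolator
    emulator: object  # LocalGPEmulator or LowRankGPEmulator
    loss_spec: LossSpec
    dataset: Dataset
    n_outputs: int

    def predict_outputs(self, theta) -> np.ndarray:
        if self.strategy != "output":
            raise ValueError("predict_outputs requires an output-strategy bundle")
        if hasattr(self.emulator, "predict_mean"):
            return np.atleast_1d(self.emulator.predict_mean(theta))
        means, _ = self.emulator.predict(theta)
        return np.atleast_1d(means)


def _make_emulator(
    Theta: np.ndarray,
    Y: np.ndarray,
    interpolator: Interpolator,
    for_loss: bool,
    gp_options: Optional[dict],
):
    opts = dict(gp_options or {})
    if interpolator == "local_gp":
        opts.setdefault("K", 100)
        return LocalGPEmulator(Theta, Y, **opts)
    if interpolator == "lowrank_gp":
        opts.setdefault("nr", 2000)
        nr_eff = min(opts["nr"], Theta.shape[0])
        default_k = DEFAULT_LOWRANK_K_LOSS if for_loss else DEFAULT_LOWRANK_K_OUTPUT
        opts.setdefault("k", min(default_k, nr_eff))
        return LowRankGPEmulator(Theta, Y, **opts)
    raise ValueError(f"unknown interpolator {interpolator!r}")


def build_output_emulator(
    dataset: Dataset,
    interpolator: Interpolator = "local_gp",
    loss_spec: Optional[LossSpec] = None,
    gp_options: Optional[dict] = None,
) -> EmulatorBundle:
    """Fit one independent scalar emulator per simulator output column."""
    emulator = _make_emulator(
        dataset.design, dataset.outputs, interpolator, for_loss=False, gp_options=gp_options
    )
    return EmulatorBundle(
        strategy="output",
        interpolator=interpolator,
        emulator=emulator,
        loss_spec=loss_spec or LossSpec(),
        dataset=dataset,
        n_outputs=dataset.outputs.shape[1],
    )


def surrogate_output_loss(theta, bundle: EmulatorBundle, y0) -> float:
    """Loss between the emulated output vector at theta and the observation."""
    y0 = np.asarray(y0, dtype=float)
    return bundle.loss_spec(bundle.predict_outputs(theta), y0)


def build_loss_emulator(
    dataset: Dataset,
    y0,
    loss_spec: Optional[LossSpec] = None,
    interpolator: Interpolator = "local_gp",
    gp_options: Optional[dict] = None,
    reuse_emulator: Optional[LowRankGPEmulator] = None,
) -> EmulatorBundle:
    """Fit a single scalar emulator to the loss surface l(theta_n | m, y0).

    ``reuse_emulator`` lets repeated low-rank loss emulations for different
    observations share the cached kernel eigenbasis.
    """
    y0 = np.asarray(y0, dtype=float)
    if y0.shape != (dataset.outputs.shape[1],):
        raise ValueError(
            f"observation length {y0.size} does not match the {dataset.outputs.shape[1]} outputs"
        )
    spec = loss_spec or LossSpec()
    losses = spec.batch(dataset.outputs, y0)
    if reuse_emulator is not None and interpolator == "lowrank_gp":
        reuse_emulator.refit_target(losses)
        emulator = reuse_emulator
    else:
        emulator = _make_emulator(
            dataset.design, losses, interpolator, for_loss=True, gp_options=gp_options
        )
    return EmulatorBundle(
        strategy="loss",
        interpolator=interpolator,
        emulator=emulator,
        loss_spec=spec,
        dataset=dataset,
        n_outputs=dataset.outputs.shape[1],
    )


def _chained_descent(objective, x0, bounds, dim, maxiter, tol):
    """Bounded quasi-Newton descent, restarted while it keeps improving.

    Restarting resets the curvature memory, which helps L-BFGS-B follow the
    long curved valleys produced by the correlated parameters.
    """
    lo, hi = bounds
    x, fval = np.asarray(x0, dtype=float), np.inf
    res = None
    for _ in range(6):
        res = minimize(
            objective,
            x,
            method="L-BFGS-B",
            bounds=[(lo, hi)] * dim,
            options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-12},
        )
        if not np.isfinite(res.fun):
            return res
        improved = fval - res.fun > tol * max(1.0, abs(res.fun))
        x, fval = res.x, float(res.fun)
        if not improved:
            break
    return res


def multistart_minimize(
    objective: Callable[[np.ndarray], float],
    config: OptimConfig = OptimConfig(),
    dim: int = 4,
    extra_starts=None,
):
    """Bounded multistart minimization with basin-of-attraction skipping.

    Sobol-scattered starts (plus any ``extra_starts``, e.g. the best-scoring
    training design points) are ranked best-first by objective value; a
    bounded quasi-Newton descent is run from each start that does not lie in
    the basin (sphere of radius ||start - local minimum||) of a previously
    found minimum.  Returns (theta_hat, value, diagnostics).
    """
    lo, hi = config.bounds
    engine = qmc.Sobol(d=dim, scramble=True, seed=config.seed)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        starts = lo + engine.random(config.n_starts) * (hi - lo)
    if extra_starts is not None and len(extra_starts):
        starts = np.vstack([np.atleast_2d(np.asarray(extra_starts, dtype=float)), starts])
    scores = np.array([objective(s) for s in starts])
    order = np.argsort(scores, kind="stable")

    def descend(x0: np.ndarray):
        return _chained_descent(objective, x0, (lo, hi), dim, config.maxiter, config.tol)

    basins: list[tuple[np.ndarray, float]] = []
    solutions = []
    n_skipped = 0
    failures = []
    for i in order:
        start = starts[i]
        if any(np.linalg.norm(start - center) <= radius for center, radius in basins):
            n_skipped += 1
            continue
        res = descend(start)
        if not np.isfinite(res.fun):
            failures.append((i, res.message))
            continue
        basins.append((res.x.copy(), float(np.linalg.norm(start - res.x))))
        solutions.append((float(res.fun), res.x.copy(), bool(res.success)))
    if not solutions:
        raise RuntimeError(f"all optimizer starts failed: {failures}")
    solutions.sort(key=lambda s: s[0])
    best_val, best_x, _ = solutions[0]
    diagnostics = {
        "n_starts": config.n_starts,
        "n_local_runs": len(solutions),
        "n_skipped": n_skipped,
        "n_converged": sum(1 for _, _, ok in solutions if ok),
        "start_values": scores,
        "failures": failures,
    }
    return np.clip(best_x, lo, hi), best_val, diagnostics


def _central_hessian(objective, x0: np.ndarray, h: np.ndarray) -> np.ndarray:
    d = x0.size
    H = np.empty((d, d))
    f0 = objective(x0)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h[i]
        H[i, i] = (objective(x0 + ei) - 2.0 * f0 + objective(x0 - ei)) / h[i] ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                objective(x0 + ei + ej)
                - objective(x0 + ei - ej)
                - objective(x0 - ei + ej)
                + objective(x0 - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return 0.5 * (H + H.T)


def hessian_uncertainty(
    objective: Callable[[np.ndarray], float],
    theta_hat,
    n_samples: int = 1000,
    seed: int = 0,
    refs: ReferenceValues = ReferenceValues(),
    curve_grid=None,
    bounds: Tuple[float, float] = (THETA_LOWER, THETA_UPPER),
    rel_step: float = 1e-4,
):
    """Hessian-based uncertainty at a surrogate-loss minimum.

    The Hessian is estimated by central differences with per-dimension step
    ``rel_step * (upper - lower)``, repaired to positive definiteness by
    eigenvalue clipping; its inverse is the approximate covariance (a lower
    bound in the Cramer-Rao sense).  ``n_samples`` draws from
    MVN(theta_hat, H^-1) are truncated to the hyperbox by rejection and
    mapped to pointwise 95% bands on the fibre and sheet stretch-stress
    curves.  Returns (covariance, samples, (fibre_curve, sheet_curve)).
    """
    theta_hat = np.asarray(theta_hat, dtype=float).reshape(-1)
    lo, hi = bounds
    h = np.full(theta_hat.size, rel_step * (hi - lo))
    H = _central_hessian(objective, theta_hat, h)

    w, V = np.linalg.eigh(H)
    w_max = float(np.max(np.abs(w)))
    if not np.isfinite(w_max) or w_max <= 0:
        raise np.linalg.LinAlgError(
            "Hessian numerically singular; consider profiling identifiable directions"
        )
    # Floor flat directions at an sd of 10 box widths: beyond that the
    # truncated distribution inside the hyperbox is indistinguishable from
    # flat, and rejection sampling stays feasible.
    floor = max(1e-10 * w_max, (10.0 * (hi - lo)) ** -2)
    w_clipped = np.maximum(w, floor)
    covariance = (V / w_clipped) @ V.T
    covariance = 0.5 * (covariance + covariance.T)

    rng = np.random.default_rng(seed)
    scale = V / np.sqrt(w_clipped)  # covariance = scale @ scale.T
    samples = np.empty((n_samples, theta_hat.size))
    filled = 0
    drawn = 0
    batch = max(4 * n_samples, 256)
    # a nearly flat loss direction gives a huge sd and a tiny acceptance
    # rate; grow the batch size adaptively before declaring the Hessian
    # effectively singular
    while filled < n_samples and drawn < 5_000_000:
        draw = theta_hat + rng.standard_normal((batch, theta_hat.size)) @ scale.T
        drawn += batch
        keep = draw[np.all((draw >= lo) & (draw <= hi), axis=1)]
        take = min(keep.shape[0], n_samples - filled)
        samples[filled : filled + take] = keep[:take]
        filled += take
        batch = min(2 * batch, 200_000)
    if filled < n_samples:
        raise np.linalg.LinAlgError(
            "truncated MVN acceptance is negligible: the Hessian is numerically "
            "singular along some direction; consider profiling the identifiable "
            "directions instead"
        )

    if curve_grid is None:
        curve_grid = np.linspace(1.0, 1.3, 31)
    curve_grid = np.asarray(curve_grid, dtype=float)
    bands = []
    for direction in ("fibre", "sheet"):
        point = stretch_stress_curve(theta_hat, refs, direction, curve_grid).stresses
        sampled = np.vstack(
            [stretch_stress_curve(s, refs, direction, curve_grid).stresses for s in samples]
        )
        lo_band = np.minimum(np.percentile(sampled, 2.5, axis=0), point)
        hi_band = np.maximum(np.percentile(sampled, 97.5, axis=0), point)
        bands.append(
            StretchStressCurve(
                direction=direction,
                stretches=curve_grid,
                stresses=point,
                lower=lo_band,
                upper=hi_band,
            )
        )
    return covariance, samples, tuple(bands)


@dataclass
class InferenceResult:
    """A point estimate with its optimization and uncertainty diagnostics."""

    theta_hat: np.ndarray
    loss_min: float
    n_starts_converged: int
    hessian: Optional[np.ndarray] = None
    covariance: Optional[np.ndarray] = None
    mvn_samples: Optional[np.ndarray] = None
    fibre_band: Optional[StretchStressCurve] = None
    sheet_band: Optional[StretchStressCurve] = None
    diagnostics: dict = field(default_factory=dict)


def estimate_parameters(
    y0,
    dataset: Dataset,
    strategy: Strategy = "output",
    interpolator: Interpolator = "local_gp",
    loss_spec: Optional[LossSpec] = None,
    optim_config: OptimConfig = OptimConfig(),
    uq: bool = True,
    n_samples: int = 1000,
    refs: ReferenceValues = ReferenceValues(),
    gp_options: Optional[dict] = None,
    bundle: Optional[EmulatorBundle] = None,
) -> InferenceResult:
    """End-to-end estimation of the reduced parameters from one observation.

    A prebuilt output-strategy ``bundle`` may be supplied to amortize emulator
    training across observations (the point of output emulation).
    """
    y0 = np.asarray(y0, dtype=float).reshape(-1)
    if y0.shape != (dataset.outputs.shape[1],):
        raise ValueError(
            f"observation length {y0.size} does not match the {dataset.outputs.shape[1]} outputs"
        )
    if strategy == "output":
        if bundle is None:
            bundle = build_output_emulator(dataset, interpolator, loss_spec, gp_options)

        def objective(theta: np.ndarray) -> float:
            return surrogate_output_loss(theta, bundle, y0)

    elif strategy == "loss":
        bundle = build_loss_emulator(dataset, y0, loss_spec, interpolator, gp_options)

        def objective(theta: np.ndarray) -> float:
            return float(bundle.emulator.predict_mean(theta))

    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    # Stage-1-style trial scoring: the training design is a precomputed set
    # of scored candidates, so descents also start from the rows whose true
    # simulated outputs best match the observation.
    spec = bundle.loss_spec
    training_losses = spec.batch(dataset.outputs, y0)
    best_rows = np.argsort(training_losses, kind="stable")[:5]
    extra_starts = dataset.design[best_rows]

    theta_hat, loss_min, diagnostics = multistart_minimize(
        objective, optim_config, extra_starts=extra_starts
    )
    # Polish: local-GP emulators cache neighbour sets fitted up to move_tol
    # away; refreshing at the incumbent optimum and re-descending removes the
    # staleness bias of the cached surface at the minimum.
    emulator = bundle.emulator
    if hasattr(emulator, "_refresh"):
        for _ in range(3):
            emulator._refresh(np.asarray(theta_hat, dtype=float), refit_hyper=True)
            res = _chained_descent(
                objective,
                theta_hat,
                optim_config.bounds,
                4,
                optim_config.maxiter,
                optim_config.tol,
            )
            if not np.isfinite(res.fun):
                break
            moved = float(np.linalg.norm(res.x - theta_hat))
            theta_hat, loss_min = np.clip(res.x, *optim_config.bounds), float(res.fun)
            if moved < 1e-6:
                break
    result = InferenceResult(
        theta_hat=theta_hat,
        loss_min=loss_min,
        n_starts_converged=diagnostics["n_converged"],
        diagnostics=diagnostics,
    )
    if uq:
        h = 1e-4 * (optim_config.bounds[1] - optim_config.bounds[0])
        hess = _central_hessian(objective, theta_hat, np.full(4, h))
        result.hessian = hess
        covariance, samples, (fib, sheet) = hessian_uncertainty(
            objective,
            theta_hat,
            n_samples=n_samples,
            seed=optim_config.seed,
            refs=refs,
            bounds=optim_config.bounds,
        )
        result.covariance = covariance
        result.mvn_samples = samples
        result.fibre_band = fib
        result.sheet_band = sheet
    return result
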