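"""Local K-nearest-neighbour Gaussian-process regression.

Full GP regression on N = 10^4 training points is ruled out by the O(N^3)
cost of the covariance factorization, so each prediction uses only the K
training points nearest (Euclidean, in raw theta-space) to the query: subset,
re-estimate the kernel hyperparameters on the local set by maximizing the log
marginal likelihood, and apply the textbook GP predictive equations with a
constant mean.  The kernel is the automatic-relevance-determination squared
exponential with one length scale per input dimension; the observation noise
standard deviation is initialized small (1e-2, the model being deterministic)
and optimized with a floor of 1e-6.

:class:`LocalGPEmulator` wraps this per-query procedure for use inside an
optimizer, caching the neighbour set and hyperparameters until the query has
moved far enough to make them stale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.optimize import minimize

__all__ = [
    "KernelHyperparams",
    "LocalGPFit",
    "ard_se_kernel",
    "ard_se_kernel_matrix",
    "find_neighbors",
    "fit_hyperparameters",
    "gp_predict",
    "predict_local",
    "LocalGPEmulator",
]

NOISE_FLOOR = 1e-6


@dataclass(frozen=True)
class KernelHyperparams:
    """ARD squared-exponential hyperparameters plus noise and constant mean."""

    output_scale: float
    length_scales: np.ndarray
    noise_sd: float
    mean_const: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "length_scales", np.atleast_1d(np.asarray(self.length_scales, dtype=float))
        )
        if self.output_scale <= 0 or self.noise_sd <= 0 or np.any(self.length_scales <= 0):
            raise ValueError("all scale hyperparameters must be strictly positive")


def ard_se_kernel(x, y, hp: KernelHyperparams) -> float:
    """output_scale^2 * exp(-1/2 sum_d ((x_d-y_d)/l_d)^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal dimension")
    z = (x - y) / hp.length_scales
    return hp.output_scale**2 * float(np.exp(-0.5 * z @ z))


def ard_se_kernel_matrix(X, Y, hp: KernelHyperparams) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float)) / hp.length_scales
    Y = np.atleast_2d(np.asarray(Y, dtype=float)) / hp.length_scales
    sq = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(Y**2, axis=1)[None, :]
        - 2.0 * X @ Y.T
    )
    return hp.output_scale**2 * np.exp(-0.5 * np.maximum(sq, 0.0))


def find_neighbors(theta_star, Theta, K: int) -> np.ndarray:
    """Indices of the K nearest training rows; ties broken by lower index."""
    Theta = np.asarray(Theta, dtype=float)
    n = Theta.shape[0]
    if K > n:
        raise ValueError(f"K={K} exceeds the number of training points {n}")
    d = np.linalg.norm(Theta - np.asarray(theta_star, dtype=float)[None, :], axis=1)
    order = np.argsort(d, kind="stable")
    return order[:K]


def _nll_and_grad(log_params, diffs_sq, y_centered, fix_noise):
    """Negative log marginal likelihood and gradient w.r.t. log hyperparameters.

    log_params = [log s, log l_1..l_d] (+ [log sigma] unless fix_noise).
    diffs_sq has shape (n, n, d) holding (x_id - x_jd)^2.
    """
    n, _, d = diffs_sq.shape
    log_s = log_params[0]
    log_l = log_params[1 : 1 + d]
    sigma = fix_noise if fix_noise is not None else np.exp(log_params[1 + d])
    s2 = np.exp(2.0 * log_s)
    inv_l2 = np.exp(-2.0 * log_l)

    Q = np.tensordot(diffs_sq, inv_l2, axes=(2, 0))  # sum_d (dx_d / l_d)^2
    K = s2 * np.exp(-0.5 * Q)
    C = K + (sigma**2) * np.eye(n)
    jitter = 0.0
    while True:
        try:
            L = cholesky(C + jitter * np.eye(n), lower=True)
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-10)
            if jitter > 1e-2:
                raise
    alpha = cho_solve((L, True), y_centered)
    nll = (
        0.5 * float(y_centered @ alpha)
        + float(np.sum(np.log(np.diag(L))))
        + 0.5 * n * np.log(2.0 * np.pi)
    )
    Cinv = cho_solve((L, True), np.eye(n))
    M = Cinv - np.outer(alpha, alpha)  # d(nll)/dC up to the 1/2 trace rule

    grad = np.empty_like(log_params)
    grad[0] = 0.5 * float(np.sum(M * (2.0 * K)))
    for j in range(d):
        dC = K * diffs_sq[:, :, j] * inv_l2[j]
        grad[1 + j] = 0.5 * float(np.sum(M * dC))
    if fix_noise is None:
        grad[1 + d] = 0.5 * float(np.trace(M)) * 2.0 * sigma**2
    return nll, grad


def _default_init(X: np.ndarray, y: np.ndarray) -> KernelHyperparams:
    spans = np.ptp(X, axis=0)
    ls = np.where(spans > 1e-8, spans / 2.0, 1.0)
    sy = float(np.std(y))
    return KernelHyperparams(
        output_scale=sy if sy > 0 else 1.0,
        length_scales=ls,
        noise_sd=1e-2,
        mean_const=float(np.mean(y)),
    )


def log_marginal_likelihood(X, y, hp: KernelHyperparams) -> float:
    """Log marginal likelihood of the data under fixed hyperparameters."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    diffs = X[:, None, :] - X[None, :, :]
    p = np.concatenate(
        [[np.log(hp.output_scale)], np.log(hp.length_scales), [np.log(hp.noise_sd)]]
    )
    nll, _ = _nll_and_grad(p, diffs**2, y - hp.mean_const, None)
    return -nll


def fit_hyperparameters(
    X,
    y,
    init: Optional[KernelHyperparams] = None,
    fix_noise: Optional[float] = None,
    maxiter: int = 60,
) -> KernelHyperparams:
    """Maximize the log marginal likelihood over (output scale, ARD lengths[, noise]).

    The constant mean is set to the sample mean of the targets.  Quasi-Newton
    (L-BFGS-B) in log-parameter space with a noise floor of 1e-6.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).reshape(-1)
    n, d = X.shape
    if n < 2:
        raise ValueError("need at least two points to fit hyperparameters")
    mean_const = float(np.mean(y))
    yc = y - mean_const
    if float(np.std(y)) < 1e-13 * (1.0 + abs(mean_const)):
        # degenerate constant targets: any kernel interpolates; keep init scales
        base = init or _default_init(X, y)
        return replace(base, output_scale=max(base.output_scale, 1e-8), mean_const=mean_const)

    # A supplied init is a warm start; the default init is always tried as
    # well, since warm starts from a distant query can sit in a poor local
    # optimum of the marginal likelihood.
    inits = [init] if init is not None else []
    inits.append(_default_init(X, y))
    bounds = [(np.log(1e-6 * max(np.std(y), 1e-8)), np.log(1e4 * max(np.std(y), 1e-8)))]
    spans = np.maximum(np.ptp(X, axis=0), 1e-6)
    bounds += [(np.log(1e-3 * s), np.log(1e3 * s)) for s in spans]
    if fix_noise is None:
        bounds.append((np.log(NOISE_FLOOR), np.log(1e2 * max(np.std(y), 1.0))))
    lo_b = np.array([b[0] for b in bounds])
    hi_b = np.array([b[1] for b in bounds])

    diffs_sq = (X[:, None, :] - X[None, :, :]) ** 2
    candidates = []
    for start in inits:
        p0 = np.concatenate([[np.log(start.output_scale)], np.log(start.length_scales)])
        if fix_noise is None:
            p0 = np.concatenate([p0, [np.log(max(start.noise_sd, NOISE_FLOOR))]])
        p0 = np.clip(p0, lo_b, hi_b)
        res = minimize(
            _nll_and_grad,
            p0,
            args=(diffs_sq, yc, fix_noise),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter},
        )
        candidates.append((_nll_and_grad(p0, diffs_sq, yc, fix_noise)[0], p0))
        if np.isfinite(res.fun):
            candidates.append((float(res.fun), res.x))
    _, p = min(candidates, key=lambda c: c[0])
    if not np.all(np.isfinite(p)):
        raise RuntimeError("hyperparameter optimization produced non-finite values")
    noise = fix_noise if fix_noise is not None else float(np.exp(p[1 + d]))
    return KernelHyperparams(
        output_scale=float(np.exp(p[0])),
        length_scales=np.exp(p[1 : 1 + d]),
        noise_sd=max(noise, NOISE_FLOOR),
        mean_const=mean_const,
    )


@dataclass
class LocalGPFit:
    """Cached local fit: neighbour set, hyperparameters and factorization."""

    indices: np.ndarray
    hyperparams: KernelHyperparams
    X: np.ndarray
    chol: tuple
    alpha: np.ndarray


def _fit_factorization(X, y, hp: KernelHyperparams) -> Tuple[tuple, np.ndarray]:
    n = X.shape[0]
    C = ard_se_kernel_matrix(X, X, hp) + hp.noise_sd**2 * np.eye(n)
    jitter = 0.0
    while True:
        try:
            factor = cho_factor(C + jitter * np.eye(n), lower=True)
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-10)
            if jitter > 1e-2:
                raise np.linalg.LinAlgError(
                    "local covariance not positive-definite after jitter escalation"
                )
    alpha = cho_solve(factor, np.asarray(y, dtype=float) - hp.mean_const)
    return factor, alpha


def gp_predict(X, y, hp: KernelHyperparams, x_star) -> Tuple[float, float]:
    """Textbook GP predictive mean and (latent) variance under fixed hyperparameters."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    factor, alpha = _fit_factorization(X, np.asarray(y, dtype=float), hp)
    k = ard_se_kernel_matrix(np.atleast_2d(x_star), X, hp)[0]
    mean = hp.mean_const + float(k @ alpha)
    v = cho_solve(factor, k)
    var = hp.output_scale**2 - float(k @ v)
    return mean, max(var, 0.0)


def predict_local(
    theta_star,
    Theta,
    y,
    K: int = 100,
    init: Optional[KernelHyperparams] = None,
    hyperparams: Optional[KernelHyperparams] = None,
) -> Tuple[float, float]:
    """Local-GP prediction at a single query point.

    Finds the K nearest neighbours, refits the hyperparameters on the local
    set (unless fixed ``hyperparams`` are supplied) and returns the GP
    predictive mean and variance.
    """
    Theta = np.asarray(Theta, dtype=float)
    y = np.asarray(y, dtype=float)
    idx = find_neighbors(theta_star, Theta, K)
    Xl, yl = Theta[idx], y[idx]
    hp = hyperparams if hyperparams is not None else fit_hyperparameters(Xl, yl, init=init)
    if hyperparams is not None:
        hp = replace(hp, mean_const=float(np.mean(yl)))
    return gp_predict(Xl, yl, hp, theta_star)


def median_nn_spacing(Theta, sample: int = 500, seed: int = 0) -> float:
    """Median nearest-neighbour distance of the design (subsampled estimate)."""
    from scipy.spatial import cKDTree

    Theta = np.asarray(Theta, dtype=float)
    tree = cKDTree(Theta)
    if Theta.shape[0] > sample:
        rng = np.random.default_rng(seed)
        query = Theta[rng.choice(Theta.shape[0], sample, replace=False)]
    else:
        query = Theta
    dist, _ = tree.query(query, k=2)
    return float(np.median(dist[:, 1]))


class LocalGPEmulator:
    """Local-GP predictor with neighbour/hyperparameter caching across queries.

    Supports a single target column or a matrix of targets (one independent
    GP per column sharing the neighbour set, since neighbours depend only on
    the inputs).  ``cache_mode``:

    - ``"on_move"`` (default): the neighbour set is refreshed once the query
      moves more than ``move_tol`` (default half the median nearest-neighbour
      spacing) from every cached reference query (a small LRU of recent
      regions absorbs line-search bouncing).  Hyperparameters are refit only
      when the query moves more than ``hyper_tol`` from every fitted anchor;
      the default (infinity) fits them once per query point, which the final
      polish step of the estimation loop complements with a fresh refit at
      the incumbent optimum.
    - ``"exact"``: full refit at every prediction (Algorithm semantics, slow).
    """

    def __init__(
        self,
        Theta,
        Y,
        K: int = 100,
        cache_mode: str = "on_move",
        move_tol: Optional[float] = None,
        hyper_tol: Optional[float] = None,
        fit_maxiter: int = 40,
    ) -> None:
        self.Theta = np.asarray(Theta, dtype=float)
        Y = np.asarray(Y, dtype=float)
        self.Y = Y[:, None] if Y.ndim == 1 else Y
        self.scalar = Y.ndim == 1
        self.K = min(K, self.Theta.shape[0])
        if cache_mode not in ("on_move", "exact"):
            raise ValueError(f"unknown cache_mode {cache_mode!r}")
        self.cache_mode = cache_mode
        if move_tol is None:
            move_tol = 0.5 * median_nn_spacing(self.Theta)
        self.move_tol = move_tol
        self.hyper_tol = hyper_tol if hyper_tol is not None else np.inf
        self.fit_maxiter = fit_maxiter
        self.max_cached_regions = 64
        self._regions: list = []  # most-recently-used first
        self.n_neighbor_refreshes = 0
        self.n_hyper_refits = 0

    def _build_region(self, theta: np.ndarray, hps: Optional[list]) -> dict:
        """Fit (or reuse) per-column local GPs around a reference query."""
        idx = find_neighbors(theta, self.Theta, self.K)
        Xl = self.Theta[idx]
        self.n_neighbor_refreshes += 1
        fits = []
        new_hps = []
        for j in range(self.Y.shape[1]):
            yl = self.Y[idx, j]
            if hps is None:
                hp = fit_hyperparameters(Xl, yl, maxiter=self.fit_maxiter)
                self.n_hyper_refits += 1
            elif hps == "warm":
                warm = self._regions[0]["hps"][j] if self._regions else None
                hp = fit_hyperparameters(Xl, yl, init=warm, maxiter=self.fit_maxiter)
                self.n_hyper_refits += 1
            else:
                hp = replace(hps[j], mean_const=float(np.mean(yl)))
            factor, alpha = _fit_factorization(Xl, yl, hp)
            new_hps.append(hp)
            fits.append(LocalGPFit(indices=idx, hyperparams=hp, X=Xl, chol=factor, alpha=alpha))
        return {
            "ref": theta.copy(),
            "hyper_ref": theta.copy() if hps in (None, "warm") else None,
            "hps": new_hps,
            "fits": fits,
            "X": Xl,
            "inv_l2": np.vstack([hp.length_scales**-2 for hp in new_hps]),
            "s2": np.array([hp.output_scale**2 for hp in new_hps]),
            "means": np.array([hp.mean_const for hp in new_hps]),
            "alpha": np.column_stack([fit.alpha for fit in fits]),
        }

    def _refresh(self, theta: np.ndarray, refit_hyper: bool) -> None:
        """Force a fresh fit at ``theta`` (used by the final polish step)."""
        region = self._build_region(theta, None if refit_hyper else "warm")
        self._regions.insert(0, region)
        del self._regions[self.max_cached_regions :]

    def _region_for(self, theta: np.ndarray) -> dict:
        if self.cache_mode == "exact":
            return self._build_region(theta, hps="warm" if self._regions else None)
        best_i, best_d = -1, np.inf
        for i, region in enumerate(self._regions):
            d = float(np.linalg.norm(theta - region["ref"]))
            if d < best_d:
                best_i, best_d = i, d
        if best_d <= self.move_tol:
            region = self._regions.pop(best_i)
            self._regions.insert(0, region)  # LRU bump
            return region
        # need a new neighbour set; decide whether hyperparameters are stale
        hyper_src = None
        for region in self._regions:
            if region["hyper_ref"] is None:
                continue
            if float(np.linalg.norm(theta - region["hyper_ref"])) <= self.hyper_tol:
                hyper_src = region["hps"]
                break
        if hyper_src is None and self._regions:
            hyper_src = "warm"
        region = self._build_region(theta, hyper_src)
        self._regions.insert(0, region)
        del self._regions[self.max_cached_regions :]
        return region

    def predict_mean(self, theta) -> np.ndarray:
        """Vectorized predictive means for all target columns (no variances)."""
        theta = np.asarray(theta, dtype=float).reshape(-1)
        region = self._region_for(theta)
        D2 = (region["X"] - theta[None, :]) ** 2  # (K, d)
        Q = D2 @ region["inv_l2"].T  # (K, m)
        Kx = region["s2"][None, :] * np.exp(-0.5 * Q)
        means = region["means"] + np.einsum("km,km->m", Kx, region["alpha"])
        return float(means[0]) if self.scalar else means

    def predict(self, theta) -> Tuple[np.ndarray, np.ndarray]:
        theta = np.asarray(theta, dtype=float).reshape(-1)
        region = self._region_for(theta)
        means = np.empty(self.Y.shape[1])
        variances = np.empty(self.Y.shape[1])
        for j, fit in enumerate(region["fits"]):
            hp = fit.hyperparams
            k = ard_se_kernel_matrix(theta[None, :], fit.X, hp)[0]
            means[j] = hp.mean_const + float(k @ fit.alpha)
            variances[j] = max(hp.output_scale**2 - float(k @ cho_solve(fit.chol, k)), 0.0)
        if self.scalar:
            return float(means[0]), float(variances[0])
        return means, variances
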