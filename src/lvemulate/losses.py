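"""Observation-vs-prediction discrepancy functions.

Both losses are negative log-likelihoods up to additive constants and scale:
the Euclidean loss assumes i.i.d. Gaussian errors with standard deviation
sigma, the Mahalanobis loss a multivariate Gaussian with a fixed covariance
Sigma, estimated once from the training outputs to capture the spatial
correlation between segment strains (and the scale gap to the volume).
Constants that do not depend on theta are dropped: they cannot move the
argmin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "LossSpec",
    "euclidean_loss",
    "mahalanobis_loss",
    "output_covariance",
]


def euclidean_loss(y_hat, y0, sigma: float = 1.0) -> float:
    """(1/2 sigma^2) ||y_hat - y0||^2."""
    y_hat = np.asarray(y_hat, dtype=float)
    y0 = np.asarray(y0, dtype=float)
    if y_hat.shape != y0.shape:
        raise ValueError(f"length mismatch: {y_hat.shape} vs {y0.shape}")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    r = y_hat - y0
    return float(r @ r) / (2.0 * sigma**2)


def _factor(Sigma: np.ndarray, base_ridge: float):
    """Cholesky of Sigma with escalating ridge; raises if hopeless."""
    ridge = base_ridge
    for _ in range(8):
        try:
            return cho_factor(Sigma + ridge * np.eye(Sigma.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            ridge = max(ridge, np.finfo(float).tiny) * 10.0
    raise np.linalg.LinAlgError("covariance not positive-definite after ridge escalation")


def mahalanobis_loss(y_hat, y0, Sigma, ridge: Optional[float] = None) -> float:
    """(1/2) (y_hat-y0)^T Sigma^{-1} (y_hat-y0), via Cholesky solve."""
    y_hat = np.asarray(y_hat, dtype=float)
    y0 = np.asarray(y0, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    if y_hat.shape != y0.shape:
        raise ValueError(f"length mismatch: {y_hat.shape} vs {y0.shape}")
    if Sigma.shape != (y0.size, y0.size):
        raise ValueError("Sigma shape does not match the residual length")
    if ridge is None:
        ridge = 0.0 if np.all(np.linalg.eigvalsh(Sigma) > 0) else default_ridge(Sigma)
    r = y_hat - y0
    factor = _factor(Sigma, ridge)
    return 0.5 * float(r @ cho_solve(factor, r))


def default_ridge(Sigma: np.ndarray) -> float:
    """Diagonal inflation 1e-8 * trace/J, proportional to the average variance."""
    Sigma = np.asarray(Sigma, dtype=float)
    return 1e-8 * float(np.trace(Sigma)) / Sigma.shape[0]


def output_covariance(Y, ridge: Optional[float] = None) -> np.ndarray:
    """Unbiased sample covariance of the output matrix plus a small ridge."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[0] < 2:
        raise ValueError("need at least two output rows to estimate a covariance")
    Sigma = np.cov(Y, rowvar=False, ddof=1)
    Sigma = np.atleast_2d(Sigma)
    if ridge is None:
        ridge = default_ridge(Sigma)
        if ridge == 0.0:  # constant rows: fall back to an absolute floor
            ridge = 1e-12
    return Sigma + ridge * np.eye(Sigma.shape[0])


@dataclass
class LossSpec:
    """Which discrepancy to use and its fixed nuisance constants.

    ``Sigma`` is required for the Mahalanobis kind; use
    :func:`output_covariance` on the training outputs to build it.
    """

    kind: Literal["euclidean", "mahalanobis"] = "euclidean"
    sigma: float = 1.0
    Sigma: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.kind not in ("euclidean", "mahalanobis"):
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.kind == "mahalanobis":
            if self.Sigma is None:
                raise ValueError("mahalanobis loss requires Sigma")
            self.Sigma = np.asarray(self.Sigma, dtype=float)
            self._factor = _factor(self.Sigma, default_ridge(self.Sigma))
        else:
            self._factor = None

    def __call__(self, y_hat, y0) -> float:
        y_hat = np.asarray(y_hat, dtype=float)
        y0 = np.asarray(y0, dtype=float)
        if y_hat.shape != y0.shape:
            raise ValueError(f"length mismatch: {y_hat.shape} vs {y0.shape}")
        r = y_hat - y0
        if self.kind == "euclidean":
            return float(r @ r) / (2.0 * self.sigma**2)
        return 0.5 * float(r @ cho_solve(self._factor, r))

    def batch(self, Y_hat, y0) -> np.ndarray:
        """Loss of every row of Y_hat against y0 (vectorized)."""
        R = np.asarray(Y_hat, dtype=float) - np.asarray(y0, dtype=float)[None, :]
        if self.kind == "euclidean":
            return np.einsum("ij,ij->i", R, R) / (2.0 * self.sigma**2)
        S = cho_solve(self._factor, R.T).T
        return 0.5 * np.einsum("ij,ij->i", R, S)
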