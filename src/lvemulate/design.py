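"""Space-filling experimental design over the reduced-parameter hyperbox.

Training inputs for the emulators are taken from a Sobol low-discrepancy
sequence over [0.1, 5]^4; the test set extends the same sequence so that the
combined design is itself the prefix of one Sobol stream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
from scipy.stats import qmc

from .ho import THETA_LOWER, THETA_UPPER

__all__ = [
    "DesignSpec",
    "DesignMatrix",
    "sobol_unit_sequence",
    "scale_to_bounds",
    "make_design",
    "make_train_test_design",
    "write_design",
    "read_design",
]


@dataclass(frozen=True)
class DesignSpec:
    """Specification of a Sobol design.

    ``skip`` drops that many initial points of the sequence (burn-in);
    ``scramble`` applies Owen scrambling with ``seed``.  Defaults are the
    unscrambled sequence with no burn-in, for cross-run reproducibility.
    """

    n_points: int
    dims: int = 4
    lower: float = THETA_LOWER
    upper: float = THETA_UPPER
    skip: int = 0
    scramble: bool = False
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.dims < 1:
            raise ValueError("dims must be >= 1")
        if not self.lower < self.upper:
            raise ValueError("lower bound must be strictly below upper bound")
        if self.skip < 0:
            raise ValueError("skip must be non-negative")


@dataclass(frozen=True)
class DesignMatrix:
    """An ordered set of parameter vectors plus its provenance."""

    points: np.ndarray
    spec: DesignSpec
    index_start: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", np.asarray(self.points, dtype=float))

    def __len__(self) -> int:
        return self.points.shape[0]

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.points, dtype=dtype)


def sobol_unit_sequence(spec: DesignSpec) -> np.ndarray:
    """First ``n_points`` of the (skipped, optionally scrambled) Sobol sequence in [0,1)^d."""
    if spec.dims > qmc.Sobol.MAXDIM:
        raise ValueError(f"Sobol generator supports at most {qmc.Sobol.MAXDIM} dimensions")
    engine = qmc.Sobol(d=spec.dims, scramble=spec.scramble, seed=spec.seed)
    if spec.skip:
        engine.fast_forward(spec.skip)
    with warnings.catch_warnings():
        # balance warning for non power-of-two sample sizes is expected here
        warnings.simplefilter("ignore", UserWarning)
        return engine.random(spec.n_points)


def scale_to_bounds(unit_points: np.ndarray, lower: float, upper: float) -> np.ndarray:
    """Affine map of unit-cube points onto [lower, upper] componentwise."""
    unit_points = np.asarray(unit_points, dtype=float)
    return lower + unit_points * (upper - lower)


def make_design(spec: DesignSpec) -> DesignMatrix:
    """Sobol design scaled onto the spec's bounds."""
    unit = sobol_unit_sequence(spec)
    return DesignMatrix(points=scale_to_bounds(unit, spec.lower, spec.upper), spec=spec)


def make_train_test_design(
    n_train: int,
    n_test: int,
    spec: Optional[DesignSpec] = None,
) -> Tuple[DesignMatrix, DesignMatrix]:
    """Training design plus a test design continuing the same Sobol stream.

    The test rows are sequence indices n_train .. n_train+n_test-1, so the
    concatenation of the two designs equals a single design of n_train+n_test
    points.
    """
    if n_train < 1 or n_test < 1:
        raise ValueError("n_train and n_test must be >= 1")
    if spec is None:
        spec = DesignSpec(n_points=n_train)
    full = sobol_unit_sequence(replace(spec, n_points=n_train + n_test))
    train = DesignMatrix(
        points=scale_to_bounds(full[:n_train], spec.lower, spec.upper),
        spec=replace(spec, n_points=n_train),
    )
    test = DesignMatrix(
        points=scale_to_bounds(full[n_train:], spec.lower, spec.upper),
        spec=replace(spec, n_points=n_test),
        index_start=n_train,
    )
    return train, test


def write_design(design: DesignMatrix, path) -> None:
    import pandas as pd

    cols = [f"theta{i + 1}" for i in range(design.points.shape[1])]
    pd.DataFrame(design.points, columns=cols).to_csv(path, index=False)


def read_design(path) -> np.ndarray:
    import pandas as pd

    frame = pd.read_csv(path)
    cols = [c for c in frame.columns if c.startswith("theta")]
    if not cols:
        raise ValueError(f"{path}: no theta columns found")
    return frame[cols].to_numpy(dtype=float)
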