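"""Deterministic toy left-ventricle simulator.

Stands in for the finite-element forward model m(theta): each of 24 wall
segments is loaded by a fixed end-diastolic pressure p_j (kPa) and responds
with a stretch lambda_j obtained by balancing the Holzapfel-Ogden Cauchy
stress against the load under incompressible uniaxial extension.  Segment
strains are reported in the Green convention, e_j = (lambda_j^2 - 1)/2, and
the cavity volume is a cubic function of the mean stretch increment so that
the 25th output lives on a very different scale from the strains — the
feature that makes the Mahalanobis/Euclidean loss comparison non-trivial.

Regional heterogeneity is emulated by giving each segment its own fibre
angle alpha_j relative to the loading (circumferential) axis, mimicking the
transmural/regional fibre rotation that makes the segments of the real
ventricle respond with different mixtures of the isotropic, fibre, sheet and
fibre-sheet energy terms.  With f0 = (cos a, sin a, 0), s0 = (-sin a, cos a,
0) and F = diag(lambda, lambda^-1/2, lambda^-1/2) the invariants are

    I1 = lam^2 + 2/lam,           I4f = c^2 lam^2 + s^2 / lam,
    I4s = s^2 lam^2 + c^2 / lam,  I8fs = s c (1/lam - lam^2),

so the fibre-sheet coupling multiplier theta4 influences every segment
(weakly, through I8fs) and the angles decorrelate the parameter effects
enough for the inverse problem to be solvable.  For angles below ~54 degrees each
energy term has a non-negative, theta-monotone contribution to the stress,
so every output is smooth in theta and strictly decreasing in each theta
component: stiffer tissue deforms less.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .design import DesignMatrix, DesignSpec, make_train_test_design
from .ho import HOParameters, ReferenceValues, reduce_parameters, validate_theta

__all__ = [
    "SimulatorConfig",
    "Dataset",
    "default_segment_loads",
    "default_segment_angles",
    "simulate_output",
    "simulate_many",
    "generate_dataset",
    "add_observation_noise",
    "write_dataset",
    "read_dataset",
]

N_OUTPUTS = 25


def default_segment_loads(n_segments: int = 24) -> np.ndarray:
    """Per-segment loading pressures (kPa): increasing grid over [0.5, 2.0] with
    a small deterministic jitter that keeps the grid strictly increasing."""
    base = np.linspace(0.5, 2.0, n_segments)
    jitter = 0.015 * np.sin(2.0 + 3.1 * np.arange(n_segments))
    return base + jitter


def default_segment_angles(n_segments: int = 24) -> np.ndarray:
    """Per-segment fibre angles (radians) spanning 5 to 50 degrees.

    A permuted ramp (stride-7 modular ordering) decorrelates the angle
    profile from the monotone load profile, so the segments probe distinct
    (stretch, angle) combinations of the constitutive surface: low-angle
    segments are dominated by the fibre term, high-angle segments mix in the
    sheet and fibre-sheet coupling terms, which is what makes all four
    stiffness multipliers identifiable.  Angles stay below ~54 degrees
    (where the loaded-fibre stretch derivative could change sign), so every
    energy term contributes monotonically to the stress.
    """
    perm = (7 * np.arange(n_segments)) % n_segments
    lo, hi = np.deg2rad(5.0), np.deg2rad(50.0)
    return lo + (hi - lo) * perm / max(n_segments - 1, 1)


@dataclass(frozen=True)
class SimulatorConfig:
    n_segments: int = 24
    segment_loads: Optional[np.ndarray] = None
    segment_angles: Optional[np.ndarray] = None
    baseline_volume: float = 60.0
    stretch_max: float = 2.15
    root_tol: float = 1e-10
    refs: ReferenceValues = field(default_factory=ReferenceValues)

    def __post_init__(self) -> None:
        loads = self.segment_loads
        if loads is None:
            loads = default_segment_loads(self.n_segments)
        loads = np.asarray(loads, dtype=float)
        if loads.shape != (self.n_segments,):
            raise ValueError("segment_loads must have one entry per segment")
        if np.any(loads <= 0):
            raise ValueError("segment loads must be positive")
        object.__setattr__(self, "segment_loads", loads)
        angles = self.segment_angles
        if angles is None:
            angles = default_segment_angles(self.n_segments)
        angles = np.asarray(angles, dtype=float)
        if angles.shape != (self.n_segments,):
            raise ValueError("segment_angles must have one entry per segment")
        object.__setattr__(self, "segment_angles", angles)

    def digest(self) -> str:
        payload = {
            "n_segments": self.n_segments,
            "segment_loads": np.round(self.segment_loads, 12).tolist(),
            "segment_angles": np.round(self.segment_angles, 12).tolist(),
            "baseline_volume": self.baseline_volume,
            "stretch_max": self.stretch_max,
            "refs": vars(self.refs),
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _segment_stress(params: HOParameters, lam: float, alpha: float) -> float:
    """lambda * dPsi_hat/dlambda for uniaxial extension with fibre angle alpha.

    Incompressible kinematics F = diag(lam, lam^-1/2, lam^-1/2); the fibre
    and sheet directions lie in the loading plane at angle alpha (see the
    module docstring for the resulting invariants).  Tension-only switching
    of the I4 terms as in the constitutive module; for alpha <= 35 degrees
    the active anisotropic regions always have a positive stretch-derivative,
    so every term stiffens the response and the theta-monotonicity of the
    outputs follows.
    """
    c2 = np.cos(alpha) ** 2
    s2 = np.sin(alpha) ** 2
    sc = np.sin(alpha) * np.cos(alpha)
    inv_l = 1.0 / lam
    i1 = lam * lam + 2.0 * inv_l
    di1 = 2.0 * lam - 2.0 * inv_l * inv_l
    s = 0.5 * params.a * np.exp(params.b * (i1 - 3.0)) * di1
    i4f = c2 * lam * lam + s2 * inv_l
    if i4f > 1.0:
        di4f = 2.0 * c2 * lam - s2 * inv_l * inv_l
        s += params.af * (i4f - 1.0) * np.exp(params.bf * (i4f - 1.0) ** 2) * di4f
    i4s = s2 * lam * lam + c2 * inv_l
    if i4s > 1.0:
        di4s = 2.0 * s2 * lam - c2 * inv_l * inv_l
        s += params.as_ * (i4s - 1.0) * np.exp(params.bs * (i4s - 1.0) ** 2) * di4s
    i8 = sc * (inv_l - lam * lam)
    di8 = sc * (-inv_l * inv_l - 2.0 * lam)
    s += params.afs * i8 * np.exp(params.bfs * i8 * i8) * di8
    return lam * s


def simulate_output(theta, config: SimulatorConfig = SimulatorConfig()) -> np.ndarray:
    """Map a reduced parameter vector to 24 Green strains + end-diastolic volume.

    For each segment the stretch solves stress(lambda) = load by bracketed
    root finding on (1, stretch_max]; an unbracketed root raises a ValueError
    naming the segment.
    """
    t = validate_theta(theta)
    params = reduce_parameters(t, config.refs)
    stretches = np.empty(config.n_segments)
    for j in range(config.n_segments):
        load = config.segment_loads[j]
        alpha = config.segment_angles[j]

        def residual(lam: float, _p=params, _a=alpha, _load=load) -> float:
            return _segment_stress(_p, lam, _a) - _load

        lo, hi = 1.0 + 1e-12, config.stretch_max
        if residual(lo) > 0 or residual(hi) < 0:
            raise ValueError(
                f"segment {j}: load {load:g} kPa not bracketed by stretches "
                f"({lo:g}, {hi:g}] for theta={np.round(t, 4).tolist()}"
            )
        stretches[j] = brentq(residual, lo, hi, xtol=config.root_tol, rtol=8.9e-16)
    strains = 0.5 * (stretches**2 - 1.0)
    volume = config.baseline_volume * (1.0 + float(np.mean(stretches - 1.0))) ** 3
    return np.concatenate([strains, [volume]])


def simulate_many(Theta, config: SimulatorConfig = SimulatorConfig()) -> np.ndarray:
    Theta = np.asarray(Theta, dtype=float)
    return np.vstack([simulate_output(row, config) for row in Theta])


@dataclass
class Dataset:
    """Paired design matrix (N x 4) and simulator output matrix (N x 25)."""

    design: np.ndarray
    outputs: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.design = np.asarray(self.design, dtype=float)
        self.outputs = np.asarray(self.outputs, dtype=float)
        if self.design.ndim != 2 or self.outputs.ndim != 2:
            raise ValueError("design and outputs must be 2-d arrays")
        if self.design.shape[0] != self.outputs.shape[0]:
            raise ValueError("design and outputs must have the same number of rows")
        if np.isnan(self.design).any() or np.isnan(self.outputs).any():
            raise ValueError("dataset contains missing values")

    @property
    def n(self) -> int:
        return self.design.shape[0]


def generate_dataset(
    n_train: int,
    n_test: int,
    config: SimulatorConfig = SimulatorConfig(),
    design_spec: Optional[DesignSpec] = None,
) -> Tuple[Dataset, Dataset]:
    """Sobol train/test designs pushed through the toy simulator."""
    train_design, test_design = make_train_test_design(n_train, n_test, design_spec)
    meta = {"config": config.digest()}
    train = Dataset(
        design=train_design.points,
        outputs=simulate_many(train_design.points, config),
        metadata={**meta, "role": "train"},
    )
    test = Dataset(
        design=test_design.points,
        outputs=simulate_many(test_design.points, config),
        metadata={**meta, "role": "test"},
    )
    return train, test


def add_observation_noise(y, strain_sd: float = 0.0, volume_sd: float = 0.0, rng_seed: int = 0):
    """Gaussian measurement noise: strains and volume perturbed on their own scales."""
    if strain_sd < 0 or volume_sd < 0:
        raise ValueError("noise standard deviations must be non-negative")
    y = np.asarray(y, dtype=float).copy()
    rng = np.random.default_rng(rng_seed)
    y[..., :-1] += rng.normal(0.0, strain_sd, size=y[..., :-1].shape) if strain_sd else 0.0
    y[..., -1] += rng.normal(0.0, volume_sd, size=y[..., -1].shape) if volume_sd else 0.0
    return y


def _columns(n_strains: int):
    return (
        [f"theta{i + 1}" for i in range(4)]
        + [f"strain{j + 1:02d}" for j in range(n_strains)]
        + ["volume"]
    )


def write_dataset(dataset: Dataset, path) -> None:
    import pandas as pd

    n_strains = dataset.outputs.shape[1] - 1
    frame = pd.DataFrame(
        np.hstack([dataset.design, dataset.outputs]), columns=_columns(n_strains)
    )
    frame.to_csv(path, index=False)


def read_dataset(path) -> Dataset:
    """Read a dataset CSV (columns theta1..theta4, strain01.., volume); validates layout."""
    import pandas as pd

    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # malformed rows: surface pandas' line info
        raise ValueError(f"{path}: parse error: {exc}") from exc
    theta_cols = [c for c in frame.columns if c.startswith("theta")]
    strain_cols = sorted(c for c in frame.columns if c.startswith("strain"))
    if len(theta_cols) != 4:
        raise ValueError(f"{path}: expected 4 theta columns, found {len(theta_cols)}")
    if not strain_cols:
        raise ValueError(f"{path}: no strain columns found")
    if "volume" not in frame.columns:
        raise ValueError(f"{path}: missing 'volume' column")
    import pandas as pd

    block = frame[theta_cols + strain_cols + ["volume"]].apply(pd.to_numeric, errors="coerce")
    bad = block.isna().any(axis=1)
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise ValueError(f"{path}: non-numeric or missing cell at line {line}")
    return Dataset(
        design=block[theta_cols].to_numpy(dtype=float),
        outputs=block[strain_cols + ["volume"]].to_numpy(dtype=float),
        metadata={"path": str(path)},
    )
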