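"""Holzapfel-Ogden constitutive layer for passive myocardium.

The strain-energy function is the invariant-based orthotropic law

    Psi = a/(2b) [exp{b(I1-3)} - 1]
        + sum_{i in {f,s}} a_i/(2 b_i) [exp{b_i (I4i-1)^2} - 1]
        + a_fs/(2 b_fs) [exp{b_fs I8fs^2} - 1]
        + (K/2)(J-1)^2,

with the anisotropic I4 terms active only in tension (I4i > 1), the standard
convention for collagen-reinforced soft tissue.  The eight material constants
(a, b, a_f, b_f, a_s, b_s, a_fs, b_fs) are strongly correlated when fitted to
in-vivo strain data, so they are grouped into four dimensionless multipliers
theta_1..theta_4 of published reference values (the reduced parameterization):

    a  = theta1*a0,  b  = theta1*b0,
    af = theta2*af0, as = theta2*as0,
    bf = theta3*bf0, bs = theta3*bs0,
    afs = theta4*afs0, bfs = theta4*bfs0,      theta_i in [0.1, 5].

Uniaxial stretch-stress curves along the myocyte (fibre) and sheet directions
are the clinically interpretable summary of an inferred parameter vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

__all__ = [
    "THETA_LOWER",
    "THETA_UPPER",
    "ReferenceValues",
    "HOParameters",
    "DeformationState",
    "Invariants",
    "StretchStressCurve",
    "validate_theta",
    "reduce_parameters",
    "compute_invariants",
    "strain_energy",
    "uniaxial_cauchy_stress",
    "stretch_stress_curve",
]

#: Closed bounds of the reduced-parameter hyperbox.
THETA_LOWER = 0.1
THETA_UPPER = 5.0

Direction = Literal["fibre", "sheet"]


@dataclass(frozen=True)
class ReferenceValues:
    """Published reference constitutive constants (a-type in kPa, b-type dimensionless)."""

    a0: float = 0.22
    b0: float = 1.62
    af0: float = 2.43
    as0: float = 0.56
    bf0: float = 1.83
    bs0: float = 0.77
    afs0: float = 0.39
    bfs0: float = 1.70

    def __post_init__(self) -> None:
        for name in ("a0", "b0", "af0", "as0", "bf0", "bs0", "afs0", "bfs0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"reference value {name} must be strictly positive")


@dataclass(frozen=True)
class HOParameters:
    """The eight constitutive constants of the orthotropic law.

    ``as_`` carries a trailing underscore only to avoid the Python keyword.
    a-type entries are stresses (kPa); b-type entries are dimensionless
    exponential rates.
    """

    a: float
    b: float
    af: float
    bf: float
    as_: float
    bs: float
    afs: float
    bfs: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "af", "bf", "as_", "bs", "afs", "bfs"):
            if not getattr(self, name) > 0:
                raise ValueError(f"HO parameter {name} must be strictly positive")


def validate_theta(theta) -> np.ndarray:
    """Validate a reduced parameter vector and return it as a float array of shape (4,).

    Raises
    ------
    ValueError
        If the vector does not have exactly four components or any component
        falls outside the closed interval [0.1, 5.0]; the message names the
        offending component.
    """
    arr = np.asarray(theta, dtype=float).reshape(-1)
    if arr.shape != (4,):
        raise ValueError(f"theta must have exactly 4 components, got shape {arr.shape}")
    for i, value in enumerate(arr):
        if not (THETA_LOWER <= value <= THETA_UPPER):
            raise ValueError(
                f"theta{i + 1}={value:g} outside the admissible interval "
                f"[{THETA_LOWER}, {THETA_UPPER}]"
            )
    return arr


def reduce_parameters(theta, refs: ReferenceValues = ReferenceValues()) -> HOParameters:
    """Map the four multipliers theta onto the eight constitutive constants."""
    t = validate_theta(theta)
    return HOParameters(
        a=t[0] * refs.a0,
        b=t[0] * refs.b0,
        af=t[1] * refs.af0,
        as_=t[1] * refs.as0,
        bf=t[2] * refs.bf0,
        bs=t[2] * refs.bs0,
        afs=t[3] * refs.afs0,
        bfs=t[3] * refs.bfs0,
    )


@dataclass
class DeformationState:
    """A deformation gradient plus the material frame (fibre, sheet directions).

    K_pen is the bulk penalty constant enforcing near-incompressibility in the
    energy; for the kinematically isochoric protocols used by the curve
    routines the penalty term is identically zero.
    """

    F: np.ndarray
    f0: np.ndarray
    s0: np.ndarray
    k_pen: float = 1e6

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.f0 = np.asarray(self.f0, dtype=float)
        self.s0 = np.asarray(self.s0, dtype=float)
        if self.F.shape != (3, 3):
            raise ValueError("F must be a 3x3 matrix")
        if np.linalg.det(self.F) <= 0:
            raise ValueError("deformation gradient must have positive determinant")
        for name, vec in (("f0", self.f0), ("s0", self.s0)):
            if vec.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
            if abs(np.linalg.norm(vec) - 1.0) > 1e-8:
                raise ValueError(f"{name} must be a unit vector")

    @property
    def C(self) -> np.ndarray:
        """Right Cauchy-Green tensor F^T F."""
        return self.F.T @ self.F

    @property
    def J(self) -> float:
        """Volume ratio det(F)."""
        return float(np.linalg.det(self.F))


@dataclass(frozen=True)
class Invariants:
    I1: float
    I4f: float
    I4s: float
    I8fs: float


def compute_invariants(state: DeformationState) -> Invariants:
    """I1 = tr(C), I4f = f0.(C f0), I4s = s0.(C s0), I8fs = f0.(C s0)."""
    C = state.C
    return Invariants(
        I1=float(np.trace(C)),
        I4f=float(state.f0 @ C @ state.f0),
        I4s=float(state.s0 @ C @ state.s0),
        I8fs=float(state.f0 @ C @ state.s0),
    )


def strain_energy(params: HOParameters, state: DeformationState) -> float:
    """Strain energy density (kPa) including the volumetric penalty.

    The I4f and I4s exponentials contribute only under tension (I4i > 1):
    collagen fibres do not support compression.
    """
    inv = compute_invariants(state)
    psi = params.a / (2.0 * params.b) * np.expm1(params.b * (inv.I1 - 3.0))
    if inv.I4f > 1.0:
        psi += params.af / (2.0 * params.bf) * np.expm1(params.bf * (inv.I4f - 1.0) ** 2)
    if inv.I4s > 1.0:
        psi += params.as_ / (2.0 * params.bs) * np.expm1(params.bs * (inv.I4s - 1.0) ** 2)
    psi += params.afs / (2.0 * params.bfs) * np.expm1(params.bfs * inv.I8fs**2)
    psi += 0.5 * state.k_pen * (state.J - 1.0) ** 2
    return float(psi)


def uniaxial_cauchy_stress(params: HOParameters, stretch, direction: Direction = "fibre"):
    """Cauchy stress (kPa) under incompressible uniaxial extension.

    The loading axis is the fibre or the sheet direction; the deformation is
    F = diag(lambda, lambda^-1/2, lambda^-1/2) in the material frame with the
    loaded direction first, so J = 1 and the hydrostatic pressure is fixed by
    the zero-lateral-stress condition.  The result equals
    ``lambda * dPsi_hat/dlambda`` where Psi_hat(lambda) is the isochoric
    energy restricted to this kinematic path.

    Accepts a scalar or array of stretches >= 1.
    """
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam < 1.0):
        raise ValueError("stretch must be >= 1 (compression protocols unsupported)")
    if direction == "fibre":
        a_l, b_l = params.af, params.bf
    elif direction == "sheet":
        a_l, b_l = params.as_, params.bs
    else:
        raise ValueError(f"direction must be 'fibre' or 'sheet', got {direction!r}")

    # I1 = lam^2 + 2/lam along this path; transverse I4 = 1/lam <= 1 stays
    # compressive so only the loaded-direction anisotropic term is active.
    i1 = lam**2 + 2.0 / lam
    dpsi_diso = 0.5 * params.a * np.exp(params.b * (i1 - 3.0)) * (2.0 * lam - 2.0 / lam**2)
    i4 = lam**2
    active = i4 > 1.0
    dpsi_dfib = np.where(
        active,
        a_l * (i4 - 1.0) * np.exp(b_l * (i4 - 1.0) ** 2) * 2.0 * lam,
        0.0,
    )
    sigma = lam * (dpsi_diso + dpsi_dfib)
    return sigma if sigma.ndim else float(sigma)


@dataclass
class StretchStressCurve:
    """A uniaxial stretch-stress relationship, optionally with a 95% band."""

    direction: Direction
    stretches: np.ndarray
    stresses: np.ndarray
    lower: Optional[np.ndarray] = None
    upper: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.stretches = np.asarray(self.stretches, dtype=float)
        self.stresses = np.asarray(self.stresses, dtype=float)
        if self.stretches.ndim != 1 or self.stretches.shape != self.stresses.shape:
            raise ValueError("stretches and stresses must be 1-d arrays of equal length")
        if self.stretches.size > 1 and not np.all(np.diff(self.stretches) > 0):
            raise ValueError("stretch grid must be strictly increasing")

    def to_frame(self):
        """Curve (and band, if present) as a pandas DataFrame."""
        import pandas as pd

        data = {
            "direction": self.direction,
            "stretch": self.stretches,
            "stress": self.stresses,
        }
        if self.lower is not None:
            data["lo95"] = self.lower
        if self.upper is not None:
            data["hi95"] = self.upper
        return pd.DataFrame(data)


def stretch_stress_curve(
    theta,
    refs: ReferenceValues = ReferenceValues(),
    direction: Direction = "fibre",
    grid=None,
) -> StretchStressCurve:
    """Evaluate the uniaxial Cauchy stress along a stretch grid for reduced theta."""
    if grid is None:
        grid = np.linspace(1.0, 1.3, 31)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("stretch grid must be non-empty")
    if grid[0] < 1.0:
        raise ValueError("stretch grid must start at >= 1")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("stretch grid must be strictly increasing")
    params = reduce_parameters(theta, refs)
    stresses = uniaxial_cauchy_stress(params, grid, direction)
    return StretchStressCurve(direction=direction, stretches=grid, stresses=np.atleast_1d(stresses))
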