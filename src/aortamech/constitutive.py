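"""Anisotropic modified Mooney-Rivlin constitutive model for aortic tissue.

Strain energy density (stress-like constants in kPa)::

    W = c1 (I1 - 3) + c2 (I2 - 3) + D1 [exp(D2 (I1 - 3)) - 1]
        + K1/K2 { exp[K2 (I4 - 1)^2] - 1 }

with I1 = tr C, I2 = (1/2)[(tr C)^2 - C:C] the isotropic invariants of the
right Cauchy-Green tensor C = X^T X, and I4 = n_f . C n_f the squared stretch
along the collagen-fiber direction n_f (circumferential by default, so the
fiber term stiffens the hoop response).

The tissue is treated as exactly incompressible: for axisymmetric states the
hydrostatic Lagrange pressure is eliminated analytically, giving the
pressure-free stress differences

    sigma_tt - sigma_rr = lam_t dW/dlam_t,   sigma_zz - sigma_rr = lam_z dW/dlam_z

where W is restricted to principal stretches with lam_r = 1/(lam_t lam_z).
These differences are all the thick-walled inflation solver needs.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .errors import (
    DegenerateDataError,
    FitFailureError,
    InvalidKinematicsError,
    OutOfRangeDeformationError,
)

__all__ = [
    "MaterialParams",
    "Kinematics",
    "StressState",
    "strain_invariants",
    "strain_energy",
    "strain_energy_incompressible",
    "stress_difference",
    "scale_params",
    "uniaxial_stress",
    "fit_baseline_params",
    "check_uniaxial_stability",
]

# exponent cap before math.exp overflows (~709); kept conservative
_EXP_CAP = 500.0

_CIRCUMFERENTIAL = np.array([0.0, 1.0, 0.0])


@dataclass(frozen=True)
class MaterialParams:
    """Material constants of the anisotropic modified Mooney-Rivlin model.

    c1, c2, D1, K1 carry stress units (kPa); D2 and K2 are dimensionless
    exponents.  ``fiber_direction`` is a unit vector in the local
    (radial, circumferential, axial) frame.
    """

    c1: float
    c2: float
    D1: float
    D2: float
    K1: float
    K2: float
    fiber_direction: np.ndarray = field(
        default_factory=lambda: _CIRCUMFERENTIAL.copy()
    )

    def __post_init__(self):
        if self.D2 <= 0 or self.K2 <= 0:
            raise ValueError("dimensionless exponents D2, K2 must be positive")
        nf = np.asarray(self.fiber_direction, dtype=float)
        if nf.shape != (3,) or not np.isclose(np.linalg.norm(nf), 1.0, atol=1e-8):
            raise ValueError("fiber_direction must be a 3-vector of unit norm")
        object.__setattr__(self, "fiber_direction", nf)

    def __eq__(self, other):
        if not isinstance(other, MaterialParams):
            return NotImplemented
        return (
            (self.c1, self.c2, self.D1, self.D2, self.K1, self.K2)
            == (other.c1, other.c2, other.D1, other.D2, other.K1, other.K2)
            and np.array_equal(self.fiber_direction, other.fiber_direction)
        )

    __hash__ = None

    @classmethod
    def human_aorta_baseline(cls) -> "MaterialParams":
        """Baseline constants fitted to published human ascending-aorta
        stress-stretch data (R^2 = 0.73), circumferential fiber."""
        return cls(c1=-525.16, c2=165.9, D1=231.8, D2=3.5, K1=33.4, K2=12.6)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "c1_kpa": self.c1,
            "c2_kpa": self.c2,
            "D1_kpa": self.D1,
            "D2": self.D2,
            "K1_kpa": self.K1,
            "K2": self.K2,
            "fiber_direction": [float(x) for x in self.fiber_direction],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MaterialParams":
        return cls(
            c1=d["c1_kpa"], c2=d["c2_kpa"], D1=d["D1_kpa"], D2=d["D2"],
            K1=d["K1_kpa"], K2=d["K2"],
            fiber_direction=np.asarray(d.get("fiber_direction", _CIRCUMFERENTIAL)),
        )

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "MaterialParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass(frozen=True)
class Kinematics:
    """Deformation measures derived from a deformation gradient X."""

    deformation_gradient: np.ndarray
    right_cauchy_green: np.ndarray
    green_strain: np.ndarray
    principal_stretches: np.ndarray  # sorted ascending
    invariants: tuple  # (I1, I2, I4)

    @classmethod
    def from_deformation_gradient(
        cls, X: np.ndarray, fiber_direction: np.ndarray = _CIRCUMFERENTIAL
    ) -> "Kinematics":
        X = np.asarray(X, dtype=float)
        C = X.T @ X
        E = 0.5 * (C - np.eye(3))
        lam2 = np.linalg.eigvalsh(C)
        if lam2[0] <= 0:
            raise InvalidKinematicsError("deformation gradient is singular")
        I1, I2, I4 = strain_invariants(C, fiber_direction)
        return cls(X, C, E, np.sqrt(lam2), (I1, I2, I4))


@dataclass(frozen=True)
class StressState:
    """Cauchy stress (kPa) with derived principal quantities.

    ``lagrange_pressure`` is the hydrostatic multiplier that enforces exact
    incompressibility; it is bookkeeping, not a material property.
    """

    cauchy_stress: np.ndarray
    lagrange_pressure: float = 0.0

    @property
    def principal_stresses(self) -> np.ndarray:
        """Eigenvalues of the Cauchy stress, sorted descending."""
        return np.linalg.eigvalsh(self.cauchy_stress)[::-1]

    @property
    def stress_P1(self) -> float:
        """Maximal principal stress (kPa)."""
        return float(self.principal_stresses[0])


def _check_spd_symmetric(C: np.ndarray) -> np.ndarray:
    C = np.asarray(C, dtype=float)
    if C.shape != (3, 3) or not np.allclose(C, C.T, atol=1e-9):
        raise InvalidKinematicsError("C must be a symmetric 3x3 tensor")
    if np.linalg.eigvalsh(C)[0] <= 0:
        raise InvalidKinematicsError("C must be positive definite")
    return C


def strain_invariants(C, fiber_direction=_CIRCUMFERENTIAL):
    """Invariants (I1, I2, I4) of the right Cauchy-Green tensor.

    I1 = sum C_ii; I2 = (1/2)[I1^2 - C_ij C_ij]; I4 = C_ij (n_f)_i (n_f)_j.
    """
    C = _check_spd_symmetric(C)
    nf = np.asarray(fiber_direction, dtype=float)
    if not np.isclose(np.linalg.norm(nf), 1.0, atol=1e-8):
        raise InvalidKinematicsError("fiber_direction must have unit norm")
    I1 = float(np.trace(C))
    I2 = 0.5 * (I1 * I1 - float(np.sum(C * C)))
    I4 = float(nf @ C @ nf)
    return I1, I2, I4


def _energy_from_invariants(p: MaterialParams, I1, I2, I4) -> float:
    e1 = p.D2 * (I1 - 3.0)
    e4 = p.K2 * (I4 - 1.0) ** 2
    if e1 > _EXP_CAP:
        raise OutOfRangeDeformationError(
            f"isotropic exponential overflow: D2*(I1-3) = {e1:.3g} (I1 = {I1:.6g})"
        )
    if e4 > _EXP_CAP:
        raise OutOfRangeDeformationError(
            f"fiber exponential overflow: K2*(I4-1)^2 = {e4:.3g} (I4 = {I4:.6g})"
        )
    return (
        p.c1 * (I1 - 3.0)
        + p.c2 * (I2 - 3.0)
        + p.D1 * (math.exp(e1) - 1.0)
        + p.K1 / p.K2 * (math.exp(e4) - 1.0)
    )


def strain_energy(params: MaterialParams, C) -> float:
    """Strain energy density W(C) in kPa."""
    I1, I2, I4 = strain_invariants(C, params.fiber_direction)
    return _energy_from_invariants(params, I1, I2, I4)


def _incompressible_invariants(lam_t: float, lam_z: float):
    """Invariants for principal stretches (1/(lam_t lam_z), lam_t, lam_z)
    with a circumferential fiber (I4 = lam_t^2)."""
    lt2, lz2 = lam_t * lam_t, lam_z * lam_z
    lr2 = 1.0 / (lt2 * lz2)
    I1 = lt2 + lz2 + lr2
    I2 = lt2 * lz2 + 1.0 / lz2 + 1.0 / lt2
    I4 = lt2
    return I1, I2, I4


def strain_energy_incompressible(params: MaterialParams, lam_t: float, lam_z: float) -> float:
    """W restricted to incompressible axisymmetric states (kPa).

    lam_t is the circumferential stretch, lam_z the axial stretch; the radial
    stretch is 1/(lam_t lam_z)."""
    if lam_t <= 0 or lam_z <= 0:
        raise InvalidKinematicsError("principal stretches must be positive")
    return _energy_from_invariants(params, *_incompressible_invariants(lam_t, lam_z))


def stress_difference(params: MaterialParams, lam_t, lam_z):
    """Pressure-eliminated Cauchy stress differences (kPa).

    Returns (sigma_tt - sigma_rr, sigma_zz - sigma_rr) for an incompressible
    axisymmetric state with circumferential fiber; derivatives of W are
    analytic.  ``lam_t`` may be an array (broadcast against scalar lam_z).
    """
    scalar = np.isscalar(lam_t) and np.isscalar(lam_z)
    lam_t = np.asarray(lam_t, dtype=float)
    lam_z = np.asarray(lam_z, dtype=float)
    if np.any(lam_t <= 0) or np.any(lam_z <= 0):
        raise InvalidKinematicsError("principal stretches must be positive")
    lt2, lz2 = lam_t * lam_t, lam_z * lam_z
    lr2 = 1.0 / (lt2 * lz2)
    I1 = lt2 + lz2 + lr2
    I4 = lt2

    e1 = params.D2 * (I1 - 3.0)
    e4 = params.K2 * (I4 - 1.0) ** 2
    if (params.D1 != 0 and np.any(e1 > _EXP_CAP)) or (
            params.K1 != 0 and np.any(e4 > _EXP_CAP)):
        raise OutOfRangeDeformationError(
            f"exponential overflow (max I1={np.max(I1):.6g}, "
            f"max I4={np.max(I4):.6g})"
        )
    dW_dI1 = params.c1 + (params.D1 * params.D2 * np.exp(e1)
                          if params.D1 != 0 else 0.0)
    dW_dI2 = params.c2
    dW_dI4 = (2.0 * params.K1 * (I4 - 1.0) * np.exp(e4)
              if params.K1 != 0 else np.zeros_like(I4))

    # chain rule through the incompressibility constraint lam_r = 1/(lam_t lam_z)
    dI1_dlt = 2.0 * lam_t - 2.0 / (lam_t * lt2 * lz2)
    dI2_dlt = 2.0 * lam_t * lz2 - 2.0 / (lam_t * lt2)
    dI4_dlt = 2.0 * lam_t
    dI1_dlz = 2.0 * lam_z - 2.0 / (lam_z * lz2 * lt2)
    dI2_dlz = 2.0 * lam_z * lt2 - 2.0 / (lam_z * lz2)

    dW_dlt = dW_dI1 * dI1_dlt + dW_dI2 * dI2_dlt + dW_dI4 * dI4_dlt
    dW_dlz = dW_dI1 * dI1_dlz + dW_dI2 * dI2_dlz
    d_t, d_z = lam_t * dW_dlt, lam_z * dW_dlz
    if scalar:
        return float(d_t), float(d_z)
    return d_t, d_z


def scale_params(params: MaterialParams, ratio: float) -> MaterialParams:
    """Stiffness scaling by one ratio.

    Multiplies the four stress-dimensioned constants (c1, c2, D1, K1) by
    ``ratio``; the dimensionless exponents D2, K2 and the fiber direction are
    unchanged, so the response shape is preserved and every stress scales
    exactly linearly.
    """
    if ratio <= 0:
        raise ValueError(f"scaling ratio must be positive, got {ratio}")
    return replace(
        params,
        c1=params.c1 * ratio,
        c2=params.c2 * ratio,
        D1=params.D1 * ratio,
        K1=params.K1 * ratio,
    )


def uniaxial_stress(params: MaterialParams, stretch):
    """Cauchy stress (kPa) of an incompressible uniaxial extension along the
    fiber direction (circumferential strip test), lateral stresses zero.

    Principal stretches are (stretch, 1/sqrt(stretch), 1/sqrt(stretch)) with
    the fiber along the loaded axis; sigma = stretch * dW_uni/dstretch.
    """
    stretch = np.asarray(stretch, dtype=float)
    if np.any(stretch <= 0):
        raise InvalidKinematicsError("stretch must be positive")
    lam = stretch
    I1 = lam**2 + 2.0 / lam
    I4 = lam**2
    e1 = params.D2 * (I1 - 3.0)
    e4 = params.K2 * (I4 - 1.0) ** 2
    if np.any(e1 > _EXP_CAP) or np.any(e4 > _EXP_CAP):
        raise OutOfRangeDeformationError("exponential overflow in uniaxial response")
    dW_dI1 = params.c1 + params.D1 * params.D2 * np.exp(e1)
    dW_dI2 = params.c2
    dW_dI4 = 2.0 * params.K1 * (I4 - 1.0) * np.exp(e4)
    dI1 = 2.0 * lam - 2.0 / lam**2
    dI2 = 2.0 - 2.0 / lam**3
    dI4 = 2.0 * lam
    return lam * (dW_dI1 * dI1 + dW_dI2 * dI2 + dW_dI4 * dI4)


def check_uniaxial_stability(params: MaterialParams, lam_range=(1.0, 1.3), n=61) -> bool:
    """True if the incremental uniaxial stiffness d sigma/d lambda is positive
    over ``lam_range``; emits a warning (not an error) when violated, since
    printed parameter sets with negative c1 can fail this check while still
    being used as-is."""
    lams = np.linspace(lam_range[0], lam_range[1], n)
    sig = uniaxial_stress(params, lams)
    stable = bool(np.all(np.diff(sig) > 0))
    if not stable:
        warnings.warn(
            "uniaxial incremental stiffness is non-positive somewhere in "
            f"lambda in [{lam_range[0]}, {lam_range[1]}]; the parameter set is "
            "used as given",
            RuntimeWarning,
            stacklevel=2,
        )
    return stable


def load_stress_stretch_csv(path) -> np.ndarray:
    """Read (stretch, stress kPa) pairs from a 2-column CSV with header."""
    import pandas as pd

    df = pd.read_csv(path)
    return df.iloc[:, :2].to_numpy(dtype=float)


def fit_baseline_params(stress_stretch_data, init: MaterialParams):
    """Least-squares fit of the uniaxial response to (stretch, stress kPa)
    pairs.

    Returns (MaterialParams, R^2).  All six constants are free (the
    dimensionless exponents bounded positive); the fiber direction is taken
    from ``init``.
    """
    from scipy.optimize import least_squares

    data = np.asarray(stress_stretch_data, dtype=float)
    if data.ndim != 2 or data.shape[1] != 2 or data.shape[0] < 6:
        raise DegenerateDataError("need >= 6 (stretch, stress) pairs")
    lam, sig = data[:, 0], data[:, 1]
    if np.any(lam <= 0):
        raise InvalidKinematicsError("stretches must be positive")
    if np.allclose(sig, sig[0]):
        raise DegenerateDataError("stress data have zero variance; R^2 undefined")

    def pack(p):
        return np.array([p.c1, p.c2, p.D1, p.D2, p.K1, p.K2])

    def unpack(x):
        return replace(init, c1=x[0], c2=x[1], D1=x[2], D2=x[3], K1=x[4], K2=x[5])

    def resid(x):
        try:
            return uniaxial_stress(unpack(x), lam) - sig
        except OutOfRangeDeformationError:
            return np.full_like(sig, 1e6)

    lb = [-np.inf, -np.inf, -np.inf, 1e-6, -np.inf, 1e-6]
    res = least_squares(resid, pack(init), bounds=(lb, np.inf), xtol=1e-12, ftol=1e-12)
    fitted = unpack(res.x)
    ss_res = float(np.sum(res.fun**2))
    ss_tot = float(np.sum((sig - sig.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    if not res.success:
        raise FitFailureError(
            f"uniaxial fit did not converge: {res.message}",
            best_params=fitted,
            residual=math.sqrt(ss_res),
        )
    return fitted, r2
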