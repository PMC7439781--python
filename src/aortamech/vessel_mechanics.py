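"""Reduced-order structural solver: incompressible inflation-extension of a
thick-walled axisymmetric vessel.

The wall is a stack of rings.  For each ring with reference inner radius A and
outer radius B = A + h, an incompressible axisymmetric map at axial stretch
lam_z sends reference radius R to

    r(R)^2 = a^2 + (R^2 - A^2) / lam_z,

so the deformed inner radius a is the single unknown.  Radial equilibrium
d sigma_rr/dr = (sigma_tt - sigma_rr)/r with zero traction on the outer
surface reduces the balance to one scalar equation,

    P = int_a^b (sigma_tt - sigma_rr) dr / r,

solved for a by bracketed root finding.  The transmural stress profile is then
reconstructed by integrating sigma_rr inward from the outer surface.  All
quadrature points live at fixed reference radii (Gauss-Legendre across the
wall), so samples of different load states refer to the same material points
and displacement fields can be differenced state-to-state.

Stresses in kPa, pressures in kPa (gauge), lengths in mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import brentq

from .constitutive import MaterialParams, stress_difference
from .errors import (
    IncompatibleStateError,
    InvalidKinematicsError,
    NonConvergenceError,
)

__all__ = [
    "VesselGeometry",
    "RingSolution",
    "DeformedState",
    "inflate_ring",
    "solve_vessel",
    "displacement_metrics",
]

#: transmural Gauss-Legendre order
N_QUAD = 16

_PRESSURE_RTOL = 1e-10


@dataclass(frozen=True)
class VesselGeometry:
    """Axisymmetric vessel wall as ordered rings.

    Arrays (mm): ``axial_position`` strictly increasing, ``inner_radius``,
    ``thickness``.  ``configuration`` labels which load state the radii
    describe.  ``tissue_density`` (g/cm^3) is carried for completeness; the
    quasi-static solver never uses it.
    """

    axial_position: np.ndarray
    inner_radius: np.ndarray
    thickness: np.ndarray
    configuration: str = "zero_load"
    tissue_density: float = 1.06

    def __post_init__(self):
        z = np.asarray(self.axial_position, dtype=float)
        r = np.asarray(self.inner_radius, dtype=float)
        h = np.broadcast_to(np.asarray(self.thickness, dtype=float), r.shape).copy()
        if z.shape != r.shape or z.ndim != 1 or z.size < 2:
            raise ValueError("need >= 2 rings with matching array shapes")
        if np.any(np.diff(z) <= 0):
            raise ValueError("axial positions must be strictly increasing")
        if np.any(r <= 0) or np.any(h <= 0):
            raise ValueError("inner radii and thicknesses must be positive")
        if self.configuration not in ("zero_load", "diastolic", "systolic"):
            raise ValueError(f"unknown configuration {self.configuration!r}")
        object.__setattr__(self, "axial_position", z)
        object.__setattr__(self, "inner_radius", r)
        object.__setattr__(self, "thickness", h)

    @property
    def n_rings(self) -> int:
        return self.axial_position.size

    @property
    def outer_radius(self) -> np.ndarray:
        return self.inner_radius + self.thickness

    @property
    def length(self) -> float:
        return float(self.axial_position[-1] - self.axial_position[0])

    def lumen_volume(self) -> float:
        """Lumen volume (mm^3) by conical-frustum quadrature of inner radii."""
        return frustum_volume(self.axial_position, self.inner_radius)

    # -- factories ---------------------------------------------------------
    @classmethod
    def uniform_cylinder(cls, inner_radius, length, n_rings=11, thickness=2.0, **kw):
        z = np.linspace(0.0, length, n_rings)
        return cls(z, np.full(n_rings, float(inner_radius)),
                   np.full(n_rings, float(thickness)), **kw)

    @classmethod
    def tapered(cls, inlet_radius, outlet_radius, length, n_rings=13,
                thickness=2.0, **kw):
        z = np.linspace(0.0, length, n_rings)
        r = np.linspace(inlet_radius, outlet_radius, n_rings)
        return cls(z, r, np.full(n_rings, float(thickness)), **kw)

    # -- CSV I/O -----------------------------------------------------------
    def to_csv(self, path):
        import pandas as pd

        pd.DataFrame(
            {
                "axial_position_mm": self.axial_position,
                "inner_radius_mm": self.inner_radius,
                "thickness_mm": self.thickness,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, configuration="zero_load"):
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            df["axial_position_mm"].to_numpy(),
            df["inner_radius_mm"].to_numpy(),
            df["thickness_mm"].to_numpy(),
            configuration=configuration,
        )

    def to_vtk(self, path, n_circ=48):
        """Write the inner surface as legacy ASCII VTK polydata."""
        theta = np.linspace(0, 2 * math.pi, n_circ, endpoint=False)
        pts, polys = [], []
        for j, (z, r) in enumerate(zip(self.axial_position, self.inner_radius)):
            for t in theta:
                pts.append((r * math.cos(t), r * math.sin(t), z))
        for j in range(self.n_rings - 1):
            for i in range(n_circ):
                a = j * n_circ + i
                b = j * n_circ + (i + 1) % n_circ
                polys.append((a, b, b + n_circ, a + n_circ))
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\naortamech surface\nASCII\n"
                     "DATASET POLYDATA\n")
            fh.write(f"POINTS {len(pts)} float\n")
            for p in pts:
                fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
            fh.write(f"POLYGONS {len(polys)} {5 * len(polys)}\n")
            for q in polys:
                fh.write("4 " + " ".join(map(str, q)) + "\n")


def frustum_volume(z: np.ndarray, r: np.ndarray) -> float:
    """Volume of stacked conical frusta (mm^3)."""
    dz = np.diff(z)
    r0, r1 = r[:-1], r[1:]
    return float(np.sum(math.pi / 3.0 * dz * (r0**2 + r0 * r1 + r1**2)))


# cached Gauss-Legendre rule on [-1, 1]
_GL_X, _GL_W = leggauss(N_QUAD)


def _gl_nodes(lo: float, hi: float):
    mid, half = 0.5 * (hi + lo), 0.5 * (hi - lo)
    return mid + half * _GL_X, half * _GL_W


@dataclass(frozen=True)
class RingSolution:
    """Converged inflation of one ring."""

    ref_inner_radius: float
    thickness: float
    lam_z: float
    pressure: float  # kPa
    deformed_inner_radius: float
    ref_radii: np.ndarray       # quadrature sample radii, reference config
    deformed_radii: np.ndarray  # same material points, deformed config
    sigma_rr: np.ndarray        # kPa
    sigma_tt: np.ndarray
    sigma_zz: np.ndarray
    sigma_rr_inner: float = 0.0  # reconstructed traction at the inner surface
    sigma_rr_outer: float = 0.0  # outer surface, zero by construction

    @property
    def displacement(self) -> np.ndarray:
        """Radial displacement r - R at the quadrature points (mm)."""
        return self.deformed_radii - self.ref_radii

    @property
    def stress_P1(self) -> np.ndarray:
        """Maximal principal stress per sample; principal axes coincide with
        the cylindrical axes in this reduction."""
        return np.max(np.stack([self.sigma_rr, self.sigma_tt, self.sigma_zz]), axis=0)


def _pressure_integral(params, a, A, B, lam_z):
    """int_a^b (sigma_tt - sigma_rr) dr / r evaluated in reference coords."""
    Rq, wq = _gl_nodes(A, B)
    rq = np.sqrt(a * a + (Rq * Rq - A * A) / lam_z)
    dsig_t, _ = stress_difference(params, rq / Rq, lam_z)
    # dr/dR = R / (lam_z r); integrand (dsig)/r * dr/dR
    return float(np.sum(wq * dsig_t * Rq / (lam_z * rq * rq)))


def inflate_ring(
    params: MaterialParams,
    ref_inner_radius: float,
    thickness: float,
    pressure: float,
    lam_z: float = 1.0,
) -> RingSolution:
    """Solve the inflation of one thick-walled ring under internal gauge
    pressure (kPa), returning the deformed inner radius and the transmural
    stress profile.

    Raises :class:`NonConvergenceError` when no deformed radius in the search
    bracket balances the applied pressure.
    """
    A = float(ref_inner_radius)
    h = float(thickness)
    if A <= 0 or h <= 0:
        raise InvalidKinematicsError("radius and thickness must be positive")
    if lam_z <= 0:
        raise InvalidKinematicsError("axial stretch must be positive")
    if pressure < 0:
        raise InvalidKinematicsError("gauge pressure must be non-negative")
    B = A + h

    if pressure == 0.0 and lam_z == 1.0:
        Rq, _ = _gl_nodes(A, B)
        zero = np.zeros_like(Rq)
        return RingSolution(A, h, lam_z, 0.0, A, Rq, Rq.copy(), zero, zero.copy(), zero.copy())

    def residual(a):
        return _pressure_integral(params, a, A, B, lam_z) - pressure

    # bracket the root: residual(a_min) < 0 for positive pressure
    a_lo = A if lam_z == 1.0 else A * 0.7
    f_lo = residual(a_lo)
    if f_lo > 0:
        # axial extension can pre-stress the wall; search inward
        step = 0.05 * A
        a_hi, f_hi = a_lo, f_lo
        while a_lo > 0.2 * A:
            a_lo -= step
            f_lo = residual(a_lo)
            if f_lo <= 0:
                break
        else:
            raise NonConvergenceError(
                "could not bracket deformed radius from below",
                diagnostics={"A": A, "pressure": pressure},
            )
    else:
        from .errors import OutOfRangeDeformationError

        a_hi, f_hi = a_lo, f_lo
        step = 0.05 * A
        while f_hi < 0:
            step *= 1.6
            a_hi = a_hi + step
            if a_hi > 6.0 * A:
                raise NonConvergenceError(
                    "pressure beyond material range: no equilibrium radius "
                    f"below 6x reference (A={A:.3g} mm, P={pressure:.3g} kPa)",
                    diagnostics={"A": A, "pressure": pressure, "f_last": f_hi},
                )
            try:
                f_hi = residual(a_hi)
            except OutOfRangeDeformationError as err:
                raise NonConvergenceError(
                    "pressure beyond material range: strain energy overflowed "
                    f"while expanding the bracket (A={A:.3g} mm, "
                    f"P={pressure:.3g} kPa): {err}",
                    diagnostics={"A": A, "pressure": pressure,
                                 "a_reached": a_hi},
                ) from err

    a = brentq(residual, a_lo, a_hi, xtol=1e-12 * A, rtol=8.9e-16)

    # transmural samples at fixed reference radii
    Rq, _ = _gl_nodes(A, B)
    rq = np.sqrt(a * a + (Rq * Rq - A * A) / lam_z)
    dsig_t, dsig_z = stress_difference(params, rq / Rq, lam_z)

    # sigma_rr(R_i) = -int_{R_i}^{B} (dsig_t / r) dr, built with a fresh
    # quadrature per subinterval so the outer-traction condition is exact
    mid = 0.5 * (Rq + B)
    half = 0.5 * (B - Rq)
    Rs = mid[:, None] + half[:, None] * _GL_X[None, :]   # (N_QUAD, N_QUAD)
    ws = half[:, None] * _GL_W[None, :]
    rs = np.sqrt(a * a + (Rs * Rs - A * A) / lam_z)
    dt, _ = stress_difference(params, rs / Rs, lam_z)
    sigma_rr = -np.sum(ws * dt * Rs / (lam_z * rs * rs), axis=1)

    return RingSolution(A, h, lam_z, pressure, a, Rq, rq,
                        sigma_rr, sigma_rr + dsig_t, sigma_rr + dsig_z,
                        sigma_rr_inner=-_pressure_integral(params, a, A, B, lam_z),
                        sigma_rr_outer=0.0)


@dataclass(frozen=True)
class DeformedState:
    """Per-ring inflation solutions plus whole-vessel summaries."""

    geometry: VesselGeometry
    pressure: float  # kPa
    lam_z: float
    rings: tuple = field(repr=False)

    @property
    def deformed_inner_radius(self) -> np.ndarray:
        return np.array([r.deformed_inner_radius for r in self.rings])

    @property
    def displacement(self) -> np.ndarray:
        """(n_rings, N_QUAD) radial displacement from the reference
        configuration (mm)."""
        return np.stack([r.displacement for r in self.rings])

    @property
    def stress_P1(self) -> np.ndarray:
        return np.stack([r.stress_P1 for r in self.rings])

    @property
    def mean_displacement(self) -> float:
        return float(np.mean(np.abs(self.displacement)))

    @property
    def max_displacement(self) -> float:
        return float(np.max(np.abs(self.displacement)))

    @property
    def mean_stress_P1(self) -> float:
        """Average over all rings and transmural quadrature points (kPa)."""
        return float(np.mean(self.stress_P1))

    @property
    def max_stress_P1(self) -> float:
        return float(np.max(self.stress_P1))

    @property
    def lumen_volume(self) -> float:
        """Deformed lumen volume (mm^3); axial positions scale with lam_z."""
        z = self.geometry.axial_position * self.lam_z
        return frustum_volume(z, self.deformed_inner_radius)

    def deformed_geometry(self, configuration="diastolic") -> VesselGeometry:
        """Deformed configuration as a new geometry; ring thickness follows
        wall-area conservation (incompressibility at the given lam_z)."""
        a = self.deformed_inner_radius
        A = self.geometry.inner_radius
        B = self.geometry.outer_radius
        b = np.sqrt(a**2 + (B**2 - A**2) / self.lam_z)
        return VesselGeometry(
            self.geometry.axial_position * self.lam_z,
            a,
            b - a,
            configuration=configuration,
            tissue_density=self.geometry.tissue_density,
        )


def solve_vessel(
    params: MaterialParams,
    geometry: VesselGeometry,
    pressure: float,
    lam_z: float = 1.0,
) -> DeformedState:
    """Ring-by-ring inflation of the whole vessel at one gauge pressure (kPa)."""
    rings = []
    for i in range(geometry.n_rings):
        try:
            rings.append(
                inflate_ring(params, geometry.inner_radius[i],
                             geometry.thickness[i], pressure, lam_z)
            )
        except NonConvergenceError as err:
            raise NonConvergenceError(
                f"ring {i} (z={geometry.axial_position[i]:.2f} mm) failed: {err}",
                diagnostics=getattr(err, "diagnostics", {}),
            ) from err
    return DeformedState(geometry, pressure, lam_z, tuple(rings))


def displacement_metrics(state_low: DeformedState, state_high: DeformedState):
    """(mean, max) radial displacement magnitude (mm) between two load states
    of the same reference geometry, sampled at the shared material quadrature
    points."""
    if state_low.geometry.n_rings != state_high.geometry.n_rings:
        raise IncompatibleStateError("states have different ring counts")
    if not (
        np.allclose(state_low.geometry.inner_radius, state_high.geometry.inner_radius)
        and np.allclose(state_low.geometry.thickness, state_high.geometry.thickness)
    ):
        raise IncompatibleStateError("states do not share a reference geometry")
    low = np.stack([r.deformed_radii for r in state_low.rings])
    high = np.stack([r.deformed_radii for r in state_high.rings])
    u = np.abs(high - low)
    return float(np.mean(u)), float(np.max(u))
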