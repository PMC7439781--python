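"""The three inverse procedures of the patient-specific pipeline.

1. **Preshrink** — find the uniform radial shrink of the imaged (diastolic)
   geometry such that re-pressurizing the shrunk, zero-load shape to
   diastolic pressure recovers the imaged lumen volume.
2. **Material calibration** — scale the four stress-dimensioned constants by
   one ratio so the systolic-pressure lumen volume matches the CT-derived
   target.
3. **Outlet calibration** — lower the outlet pressure trace by a constant
   offset until the cycle-averaged inlet velocity matches the Doppler
   measurement.

Each stage converges its root to ~1e-3 relative and then re-verifies the 5%
relative-error contract on the target quantity, so a reported ``converged``
flag is never marginal.  All root finding is Brent's bracketed method
(safeguarded secant/inverse-quadratic with bisection fallback); the
procedures are deterministic given their inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from . import units
from .constitutive import MaterialParams, scale_params
from .errors import (
    CalibrationError,
    InfeasibleTargetError,
    NonConvergenceError,
)
from .hemodynamics import (
    BloodProperties,
    PressureAreaLaw,
    PressureWaveform,
    solve_flow,
)
from .vessel_mechanics import VesselGeometry, solve_vessel

__all__ = [
    "CalibrationResult",
    "FlowContext",
    "preshrink",
    "shrink_geometry",
    "calibrate_material",
    "calibrate_outlet",
]

#: the pipeline-wide relative-error contract for calibrated targets
CALIBRATION_TOL = 0.05


@dataclass
class CalibrationResult:
    """Outcome of one inverse stage.

    ``value`` is the calibrated parameter (shrink rate as a fraction,
    stiffness ratio, or outlet offset in mmHg); ``relative_error`` is the
    re-evaluated mismatch of the target quantity; ``trace`` records every
    objective evaluation as (value, relative_error) pairs.
    """

    parameter: str
    value: float
    relative_error: float
    iterations: int
    converged: bool
    trace: list = field(default_factory=list)

    def __post_init__(self):
        if self.converged and not self.relative_error < CALIBRATION_TOL:
            raise ValueError(
                "converged result violates the relative-error contract: "
                f"{self.relative_error:.4g} >= {CALIBRATION_TOL}"
            )

    def trace_to_csv(self, path):
        import pandas as pd

        pd.DataFrame(self.trace, columns=["value", "relative_error"]).rename_axis(
            "iteration"
        ).to_csv(path)


def shrink_geometry(in_vivo: VesselGeometry, shrink: float) -> VesselGeometry:
    """Candidate zero-load geometry: inner radii uniformly scaled by
    (1 - shrink); wall thickness follows wall-area conservation so the
    incompressible forward inflation returns the imaged wall exactly."""
    if not 0.0 <= shrink < 1.0:
        raise ValueError("shrink rate must be in [0, 1)")
    A0 = in_vivo.inner_radius * (1.0 - shrink)
    wall_area = in_vivo.outer_radius**2 - in_vivo.inner_radius**2
    B0 = np.sqrt(A0**2 + wall_area)
    return VesselGeometry(
        in_vivo.axial_position, A0, B0 - A0,
        configuration="zero_load", tissue_density=in_vivo.tissue_density,
    )


def preshrink(
    in_vivo_geometry: VesselGeometry,
    dbp_mmhg: float,
    params: MaterialParams,
    initial_shrink: float = 0.05,
    bracket: tuple = (0.0, 0.40),
    lam_z: float = 1.0,
    tol: float = CALIBRATION_TOL,
):
    """Zero-load geometry by shrink-rate calibration.

    The candidate starts at a 5% shrink and is adjusted until the candidate,
    pressurized to diastolic pressure, reproduces the in-vivo (CT) lumen
    volume.  Returns (zero-load geometry, CalibrationResult).
    """
    if dbp_mmhg < 0:
        raise ValueError("DBP must be non-negative")
    v_target = in_vivo_geometry.lumen_volume()
    trace: list = []

    if dbp_mmhg == 0:
        geom = shrink_geometry(in_vivo_geometry, 0.0)
        return geom, CalibrationResult("shrink_rate", 0.0, 0.0, 0, True, trace)

    p_kpa = units.mmhg_to_kpa(dbp_mmhg)

    def objective(s):
        vol = solve_vessel(params, shrink_geometry(in_vivo_geometry, s),
                           p_kpa, lam_z).lumen_volume
        err = vol - v_target
        trace.append((s, abs(err) / v_target))
        return err

    f_lo = objective(initial_shrink)
    if f_lo > 0:
        lo, hi = initial_shrink, bracket[1]
        f_hi = objective(hi)
        if f_hi > 0:
            raise CalibrationError(
                f"no shrink rate in [{initial_shrink}, {bracket[1]}] recovers "
                "the in-vivo volume", diagnostics={"trace": trace},
            )
    else:
        lo, hi = bracket[0], initial_shrink
        f_hi = f_lo
        f_lo = objective(lo)
        if f_lo < 0:
            raise CalibrationError(
                "pressurized candidate is smaller than the imaged vessel even "
                "with no shrink", diagnostics={"trace": trace},
            )
    s_star = brentq(objective, lo, hi, xtol=1e-6)

    geom = shrink_geometry(in_vivo_geometry, s_star)
    v_achieved = solve_vessel(params, geom, p_kpa, lam_z).lumen_volume
    rel = abs(v_achieved - v_target) / v_target
    return geom, CalibrationResult(
        "shrink_rate", s_star, rel, len(trace), rel < tol, trace)


def calibrate_material(
    geometry: VesselGeometry,
    params_init: MaterialParams,
    delta_p_kpa: float,
    v_systolic_target: float,
    ratio_bounds: tuple = (0.05, 50.0),
    lam_z: float = 1.0,
    tol: float = CALIBRATION_TOL,
):
    """Patient-specific stiffness: one ratio on the stress-dimensioned
    constants so the lumen volume under the systolic-diastolic pressure
    difference matches the CT systolic volume.

    ``geometry`` is the configuration the pressure difference is applied to
    (the imaged diastolic shape, treated as stress-free for this stage).
    Returns (scaled MaterialParams, CalibrationResult).
    """
    if delta_p_kpa <= 0:
        raise ValueError("pressure difference must be positive")
    v_ref = geometry.lumen_volume()
    if v_systolic_target <= v_ref:
        raise InfeasibleTargetError(
            f"systolic target volume {v_systolic_target:.1f} mm^3 does not "
            f"exceed the reference volume {v_ref:.1f} mm^3"
        )
    trace: list = []

    def volume(u):
        return solve_vessel(scale_params(params_init, math.exp(u)), geometry,
                            delta_p_kpa, lam_z).lumen_volume

    def objective(u):
        err = volume(u) - v_systolic_target
        trace.append((math.exp(u), abs(err) / v_systolic_target))
        return err

    u_lo, u_hi = math.log(ratio_bounds[0]), math.log(ratio_bounds[1])
    # soft end may exceed the material range; tighten until solvable
    f_lo = None
    while f_lo is None:
        try:
            f_lo = objective(u_lo)
        except NonConvergenceError:
            u_lo += 0.5
            if u_lo >= u_hi:
                raise CalibrationError(
                    "no solvable stiffness ratio bracket",
                    diagnostics={"trace": trace})
    if f_lo < 0:
        raise CalibrationError(
            "target volume unreachable even at the softest admissible wall",
            diagnostics={"trace": trace})
    f_hi = objective(u_hi)
    if f_hi > 0:
        raise CalibrationError(
            "target volume exceeded even at the stiffest admissible wall",
            diagnostics={"trace": trace})
    u_star = brentq(objective, u_lo, u_hi, xtol=1e-5)

    ratio = math.exp(u_star)
    v_achieved = volume(u_star)
    rel = abs(v_achieved - v_systolic_target) / v_systolic_target
    return scale_params(params_init, ratio), CalibrationResult(
        "stiffness_ratio", ratio, rel, len(trace), rel < tol, trace)


@dataclass(frozen=True)
class FlowContext:
    """Everything the outlet calibration needs to run the flow model."""

    tube_law: PressureAreaLaw
    blood: BloodProperties
    n_cycles: int = 2
    rtol: float = 1e-5  # coarser tolerances leave ~1% step-sequence jitter
    atol: float = 1e-6
    max_nodes: int = 5

    def mean_inlet_velocity(self, p_in: PressureWaveform, offset_mmhg: float) -> float:
        state = solve_flow(self.tube_law, self.blood, p_in,
                           p_in.shifted(offset_mmhg), n_cycles=self.n_cycles,
                           rtol=self.rtol, atol=self.atol,
                           max_nodes=self.max_nodes)
        return state.mean_inlet_velocity


def calibrate_outlet(
    p_in: PressureWaveform,
    measured_mean_inlet_velocity: float,
    context: FlowContext,
    offset_bounds: tuple = (0.0, 30.0),
    tol: float = CALIBRATION_TOL,
):
    """Outlet pressure trace p_out(t) = p_in(t) - delta with the scalar
    offset delta (mmHg) chosen so the cycle-averaged inlet velocity matches
    the Doppler measurement.  Returns (p_out, CalibrationResult)."""
    if measured_mean_inlet_velocity < 0:
        raise ValueError("measured velocity must be non-negative")
    trace: list = []
    v_meas = measured_mean_inlet_velocity

    def velocity(delta):
        return context.mean_inlet_velocity(p_in, delta)

    def objective(delta):
        err = velocity(delta) - v_meas
        trace.append((delta, abs(err) / v_meas if v_meas > 0 else abs(err)))
        return err

    if v_meas == 0:
        return p_in.shifted(0.0), CalibrationResult(
            "outlet_offset_mmhg", 0.0, 0.0, 0, True, trace)

    f0 = objective(offset_bounds[0])
    if f0 >= 0:
        # compliance pumping alone meets or exceeds the measurement
        rel = abs(f0) / v_meas
        return p_in.shifted(offset_bounds[0]), CalibrationResult(
            "outlet_offset_mmhg", offset_bounds[0], rel, len(trace),
            rel < tol, trace)
    # grow the upper bracket geometrically: physiologic measurements need
    # only small offsets, and extreme offsets can drive the wall model out
    # of its tabulated range
    hi = max(0.05, offset_bounds[0] + 0.05)
    while True:
        hi = min(hi, offset_bounds[1])
        try:
            f_hi = objective(hi)
        except StructuralRangeError as err:
            raise CalibrationError(
                f"measured velocity {v_meas:.1f} mm/s drives the wall out of "
                f"its structural range before the offset bracket closes: {err}",
                diagnostics={"trace": trace}) from err
        if f_hi >= 0:
            break
        if hi >= offset_bounds[1]:
            raise CalibrationError(
                f"measured velocity {v_meas:.1f} mm/s unreachable with outlet "
                f"offset up to {offset_bounds[1]} mmHg",
                diagnostics={"trace": trace})
        hi *= 4.0

    # the velocity-offset map is near-affine, so bracketed secant steps
    # (bisection fallback) converge in a handful of flow solves
    lo = offset_bounds[0]
    f_lo = f0
    delta_star, f_star = hi, f_hi
    for _ in range(20):
        d_sec = lo - f_lo * (hi - lo) / (f_hi - f_lo)
        if not lo < d_sec < hi:
            d_sec = 0.5 * (lo + hi)
        f_sec = objective(d_sec)
        if abs(f_sec) < abs(f_star):
            delta_star, f_star = d_sec, f_sec
        if abs(f_sec) <= 1e-3 * v_meas:
            break
        if f_sec < 0:
            lo, f_lo = d_sec, f_sec
        else:
            hi, f_hi = d_sec, f_sec
        if hi - lo < 1e-10:
            break

    rel = abs(f_star) / v_meas
    if rel >= tol:
        raise CalibrationError(
            "outlet offset iteration did not reach the velocity tolerance "
            f"(best relative error {rel:.3g})",
            diagnostics={"trace": trace})
    return p_in.shifted(delta_star), CalibrationResult(
        "outlet_offset_mmhg", delta_star, rel, len(trace), rel < tol, trace)
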