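"""Synthetic patient cohorts with hidden ground truth.

The generator draws two groups (nondilated / dilated) of demographic and
hemodynamic fields from independent truncated normals whose defaults are
anchored to the reference cohort's group summaries, derives blood viscosity
from hematocrit and total plasma protein, and equips every patient with a
hidden truth: a zero-load vessel geometry, a stiffness ratio on the baseline
wall constants (dilated walls softer), and an outlet pressure offset.

``synthesize_measurements`` then runs the forward models to manufacture the
quantities a clinic would measure — CT lumen volumes at diastole and systole
and a Doppler mean inlet velocity — plus multiplicative noise, so every
inverse-calibration stage can be tested by recovery against the truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import stats

from . import units
from .cohort_stats import PatientRecord
from .constitutive import MaterialParams, scale_params
from .errors import AortamechError, ConfigurationError
from .hemodynamics import (
    BloodProperties,
    PressureAreaLaw,
    scale_waveform,
    viscosity_from_blood,
    wiggers_template,
)
from .inverse_calibration import FlowContext
from .vessel_mechanics import VesselGeometry, solve_vessel

__all__ = [
    "FieldSpec",
    "GroupSpec",
    "CohortSpec",
    "PatientTruth",
    "PatientMeasurements",
    "generate_cohort",
    "synthesize_measurements",
]


@dataclass(frozen=True)
class FieldSpec:
    """Truncated-normal distribution of one per-patient field."""

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self):
        if self.sd < 0 or not self.lo <= self.mean <= self.hi:
            raise ConfigurationError(f"infeasible field spec {self}")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.sd == 0:
            return np.full(n, self.mean)
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                                   size=n, random_state=rng)


def _nondilated_defaults() -> dict:
    return {
        "age": FieldSpec(13.5, 6.1, 3.0, 30.0),
        "height": FieldSpec(143.0, 23.0, 95.0, 185.0),
        "weight": FieldSpec(36.3, 16.6, 12.0, 80.0),
        "sbp": FieldSpec(109.0, 16.0, 80.0, 150.0),
        "dbp": FieldSpec(66.0, 13.0, 40.0, 100.0),
        "aad": FieldSpec(25.68, 5.86, 14.0, 40.0),
        "z_score": FieldSpec(2.78, 1.27, 0.0, 4.9),
        "hematocrit": FieldSpec(50.0, 12.0, 25.0, 70.0),
        "plasma_protein": FieldSpec(7.5, 1.5, 4.5, 11.0),  # g/dL
    }


def _dilated_defaults() -> dict:
    return {
        "age": FieldSpec(11.6, 4.8, 3.0, 30.0),
        "height": FieldSpec(135.0, 24.0, 95.0, 185.0),
        "weight": FieldSpec(26.5, 12.0, 12.0, 80.0),
        "sbp": FieldSpec(107.0, 17.0, 75.0, 150.0),
        "dbp": FieldSpec(62.0, 11.0, 38.0, 100.0),
        "aad": FieldSpec(31.53, 6.38, 18.0, 45.0),
        # SD from the per-patient reference values (the summary-row SD is a
        # misprint of the nondilated one)
        "z_score": FieldSpec(8.30, 2.11, 5.0, 14.0),
        "hematocrit": FieldSpec(50.0, 12.0, 25.0, 70.0),
        "plasma_protein": FieldSpec(7.5, 1.5, 4.5, 11.0),
    }


@dataclass(frozen=True)
class GroupSpec:
    """Per-group field distributions plus the hidden-truth parameters."""

    fields: dict
    male_fraction: float
    #: median of the lognormal stiffness-ratio distribution; dilated walls
    #: are softer (median < 1)
    ratio_median: float
    ratio_log_sd: float = 0.15
    #: outlet offset range (mmHg); small offsets give physiologic
    #: 100-400 mm/s Doppler inlet velocities in the reduced flow model
    offset_range: tuple = (0.008, 0.03)


@dataclass(frozen=True)
class CohortSpec:
    """Complete recipe for a synthetic cohort; the seed is mandatory."""

    seed: int
    n_per_group: int = 10
    nondilated: GroupSpec = field(default_factory=lambda: GroupSpec(
        _nondilated_defaults(), male_fraction=0.8, ratio_median=1.15))
    dilated: GroupSpec = field(default_factory=lambda: GroupSpec(
        _dilated_defaults(), male_fraction=0.6, ratio_median=0.75))
    #: multiplicative noise SDs; the volume level is kept well below the
    #: ~4% systolic-diastolic volume change so the stiffness ratio stays
    #: identifiable from the manufactured CT volumes
    volume_noise: float = 0.005
    velocity_noise: float = 0.03
    period_s: float = 0.8
    n_rings: int = 13
    segment_length_mm: float = 60.0
    wall_thickness_mm: float = 2.0
    #: zero-load mid radius as a fraction of AAD/2 (pre-compensates the
    #: diastolic inflation)
    preshrink_fraction: float = 0.92
    taper: float = 0.05

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ConfigurationError("need n >= 2 per group")

    def to_yaml(self, path):
        def enc(gs):
            return {
                "fields": {k: vars(v) for k, v in gs.fields.items()},
                "male_fraction": gs.male_fraction,
                "ratio_median": gs.ratio_median,
                "ratio_log_sd": gs.ratio_log_sd,
                "offset_range": list(gs.offset_range),
            }

        doc = {k: getattr(self, k) for k in (
            "seed", "n_per_group", "volume_noise", "velocity_noise",
            "period_s", "n_rings", "segment_length_mm", "wall_thickness_mm",
            "preshrink_fraction", "taper")}
        doc["nondilated"] = enc(self.nondilated)
        doc["dilated"] = enc(self.dilated)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)

        def dec(d):
            return GroupSpec(
                fields={k: FieldSpec(**v) for k, v in d["fields"].items()},
                male_fraction=d["male_fraction"],
                ratio_median=d["ratio_median"],
                ratio_log_sd=d["ratio_log_sd"],
                offset_range=tuple(d["offset_range"]),
            )

        groups = {g: dec(doc.pop(g)) for g in ("nondilated", "dilated")}
        return cls(nondilated=groups["nondilated"], dilated=groups["dilated"],
                   **doc)


@dataclass(frozen=True)
class PatientTruth:
    """Hidden ground truth behind one synthetic patient."""

    zero_load_geometry: VesselGeometry
    stiffness_ratio: float
    outlet_offset_mmhg: float
    params: MaterialParams
    blood: BloodProperties


@dataclass(frozen=True)
class PatientMeasurements:
    """Manufactured clinical measurements for one patient."""

    diastolic_geometry: VesselGeometry
    v_diastolic: float          # mm^3
    v_systolic: float           # mm^3
    doppler_inlet_velocity: float  # mm/s, cycle-averaged


def generate_cohort(spec: CohortSpec):
    """Draw a cohort and its hidden truth.

    Returns (records, truth) where ``records`` is a list of PatientRecord
    (nondilated first) and ``truth`` maps patient id -> PatientTruth.
    Generation is fully determined by ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    baseline = MaterialParams.human_aorta_baseline()
    records, truth = [], {}
    pid = 0
    for group, gs in (("nondilated", spec.nondilated), ("dilated", spec.dilated)):
        n = spec.n_per_group
        draws = {k: f.draw(rng, n) for k, f in gs.fields.items()}
        sex = np.where(rng.random(n) < gs.male_fraction, "M", "F")
        ratios = np.exp(rng.normal(math.log(gs.ratio_median), gs.ratio_log_sd, n))
        offsets = rng.uniform(*gs.offset_range, n)
        # enforce SBP > DBP + 15 mmHg pairwise by redrawing the pair
        for i in range(n):
            guard = 0
            while draws["sbp"][i] < draws["dbp"][i] + 15.0:
                draws["sbp"][i] = gs.fields["sbp"].draw(rng, 1)[0]
                draws["dbp"][i] = gs.fields["dbp"].draw(rng, 1)[0]
                guard += 1
                if guard > 1000:
                    raise ConfigurationError(
                        "SBP/DBP specs cannot satisfy SBP > DBP")
        for i in range(n):
            pid += 1
            name = f"S{pid:02d}"
            visc = viscosity_from_blood(draws["hematocrit"][i],
                                        draws["plasma_protein"][i], "g/dL")
            rec = PatientRecord(
                id=name, age=float(draws["age"][i]), sex=str(sex[i]),
                height=float(draws["height"][i]), weight=float(draws["weight"][i]),
                sbp=float(draws["sbp"][i]), dbp=float(draws["dbp"][i]),
                aad=float(draws["aad"][i]), aad_z_score=float(draws["z_score"][i]),
                viscosity=visc, group=group,
            )
            mid_r = spec.preshrink_fraction * rec.aad / 2.0
            geom = VesselGeometry.tapered(
                mid_r * (1 + spec.taper), mid_r * (1 - spec.taper),
                spec.segment_length_mm, n_rings=spec.n_rings,
                thickness=spec.wall_thickness_mm,
            )
            params = scale_params(baseline, float(ratios[i]))
            blood = BloodProperties.from_blood_counts(
                draws["hematocrit"][i], draws["plasma_protein"][i], "g/dL")
            records.append(rec)
            truth[name] = PatientTruth(geom, float(ratios[i]),
                                       float(offsets[i]), params, blood)
    return records, truth


def synthesize_measurements(records, truth, spec: CohortSpec,
                            noise_seed: int | None = None):
    """Run the forward models and manufacture noisy measurements.

    Returns (measurements, excluded) where ``measurements`` maps patient
    id -> PatientMeasurements and ``excluded`` lists (id, reason) for
    patients whose forward solve failed.  The systolic volume uses the same
    convention as the material-calibration stage (pressure difference applied
    to the diastolic shape treated as stress-free); V_systolic > V_diastolic
    is enforced on the noisy values by redrawing the noise pair.
    """
    rng = np.random.default_rng(spec.seed + 1 if noise_seed is None else noise_seed)
    out, excluded = {}, []
    for rec in records:
        tr = truth[rec.id]
        try:
            dbp_kpa = units.mmhg_to_kpa(rec.dbp)
            dp_kpa = units.mmhg_to_kpa(rec.sbp - rec.dbp)
            dia_state = solve_vessel(tr.params, tr.zero_load_geometry, dbp_kpa)
            dia_geom = dia_state.deformed_geometry("diastolic")
            v_dia = dia_state.lumen_volume
            v_sys = solve_vessel(tr.params, dia_geom, dp_kpa).lumen_volume
            law = PressureAreaLaw(tr.params, tr.zero_load_geometry,
                                  p_min_mmhg=0.0, p_max_mmhg=rec.sbp + 15.0)
            p_in = scale_waveform(wiggers_template, rec.sbp, rec.dbp,
                                  period=spec.period_s)
            v_doppler = FlowContext(law, tr.blood).mean_inlet_velocity(
                p_in, tr.outlet_offset_mmhg)
        except AortamechError as err:
            excluded.append((rec.id, str(err)))
            continue
        for _ in range(1000):
            e1, e2 = rng.normal(0.0, spec.volume_noise, 2) if spec.volume_noise else (0.0, 0.0)
            nv_dia, nv_sys = v_dia * (1 + e1), v_sys * (1 + e2)
            # keep the systolic target feasible for the stiffness calibration
            if nv_sys > nv_dia and nv_sys > 1.002 * v_dia:
                break
        else:
            excluded.append((rec.id, "could not keep V_sys > V_dia under noise"))
            continue
        e3 = rng.normal(0.0, spec.velocity_noise) if spec.velocity_noise else 0.0
        out[rec.id] = PatientMeasurements(dia_geom, nv_dia, nv_sys,
                                          v_doppler * (1 + e3))
    return out, excluded
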