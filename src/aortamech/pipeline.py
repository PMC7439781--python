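"""Per-patient orchestration and cohort assembly.

``run_patient`` executes the full patient workflow: material calibration
against the systolic CT volume, preshrink to the zero-load configuration,
outlet calibration against the Doppler velocity, and the final structural and
flow solves from which the reported metric set (velocities, displacements,
wall stress, per phase) is extracted.  ``run_cohort`` maps it over a cohort,
splits by Z score if needed, and runs the two-group statistics protocol.

Material calibration runs before preshrink so the zero-load state is
constructed with the patient-specific stiffness (the imaged diastolic shape
is the input to both, so the stages are otherwise independent).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import units
from .cohort_stats import (
    PatientRecord,
    build_results_tables,
    compare_sex,
    render_table_text,
    split_by_zscore,
)
from .constitutive import MaterialParams, check_uniaxial_stability
from .errors import AortamechError, ConfigurationError
from .hemodynamics import (
    BloodProperties,
    PressureAreaLaw,
    scale_waveform,
    solve_flow,
    wiggers_template,
)
from .inverse_calibration import (
    FlowContext,
    calibrate_material,
    calibrate_outlet,
    preshrink,
)
from .vessel_mechanics import displacement_metrics, solve_vessel

__all__ = ["RunConfig", "PatientResult", "run_patient", "run_cohort"]

#: the Table 2-4 metric set extracted per patient
METRIC_COLUMNS = [
    ("inlet_velocity", "diastolic"), ("inlet_velocity", "systolic"),
    ("mean_velocity", "diastolic"), ("mean_velocity", "systolic"),
    ("max_displacement", "systolic"), ("mean_displacement", "systolic"),
    ("max_stress_p1", "diastolic"), ("max_stress_p1", "systolic"),
    ("mean_stress_p1", "diastolic"), ("mean_stress_p1", "systolic"),
]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; round-trips through YAML unchanged."""

    period_s: float = 0.8
    lam_z: float = 1.0
    protein_unit: str = "g/dL"
    alpha: float = 0.05
    strict_normality: bool = False
    calibration_tol: float = 0.05
    shrink_bracket: tuple = (0.0, 0.40)
    ratio_bounds: tuple = (0.05, 50.0)
    offset_bounds: tuple = (0.0, 30.0)
    flow_cycles: int = 2
    flow_rtol: float = 1e-5
    flow_max_nodes: int = 5
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self):
        if min(self.calibration_tol, self.flow_rtol) <= 0:
            raise ConfigurationError("tolerances must be positive")

    def to_yaml(self, path):
        doc = asdict(self)
        for k in ("shrink_bracket", "ratio_bounds", "offset_bounds"):
            doc[k] = list(doc[k])
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        for k in ("shrink_bracket", "ratio_bounds", "offset_bounds"):
            if k in doc:
                doc[k] = tuple(doc[k])
        return cls(**doc)


@dataclass
class PatientResult:
    """Metrics and calibration outcomes for one patient."""

    patient_id: str
    group: str | None
    metrics: dict                  # (metric, phase) string keys -> value
    calibration: dict              # stage -> {value, relative_error, ...}
    flags: list = field(default_factory=list)

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _calib_record(res) -> dict:
    return {
        "parameter": res.parameter,
        "value": float(res.value),
        "relative_error": float(res.relative_error),
        "iterations": int(res.iterations),
        "converged": bool(res.converged),
        "trace": [list(map(float, t)) for t in res.trace],
    }


def run_patient(record: PatientRecord, diastolic_geometry, measurements,
                config: RunConfig = RunConfig(),
                params_init: MaterialParams | None = None) -> PatientResult:
    """Calibrate and simulate one patient; returns the Table 2-4 metric set.

    ``measurements`` needs attributes ``v_diastolic``, ``v_systolic`` and
    ``doppler_inlet_velocity`` (the latter may be None, in which case the
    outlet stage is skipped and flow metrics are flagged uncalibrated).
    """
    params_init = params_init or MaterialParams.human_aorta_baseline()
    flags: list = []
    calib: dict = {}

    dp_kpa = units.mmhg_to_kpa(record.sbp - record.dbp)
    dbp_kpa = units.mmhg_to_kpa(record.dbp)
    sbp_kpa = units.mmhg_to_kpa(record.sbp)

    # 1. patient-specific stiffness from the systolic CT volume
    params, res_mat = calibrate_material(
        diastolic_geometry, params_init, dp_kpa, measurements.v_systolic,
        ratio_bounds=config.ratio_bounds, lam_z=config.lam_z,
        tol=config.calibration_tol)
    calib["material"] = _calib_record(res_mat)
    if not check_uniaxial_stability(params):
        flags.append("unstable_uniaxial_stiffness")

    # 2. zero-load configuration from the diastolic CT volume
    zero_load, res_shrink = preshrink(
        diastolic_geometry, record.dbp, params,
        bracket=config.shrink_bracket, lam_z=config.lam_z,
        tol=config.calibration_tol)
    calib["preshrink"] = _calib_record(res_shrink)

    # 3. outlet offset from the Doppler mean inlet velocity
    blood = BloodProperties(record.viscosity)
    law = PressureAreaLaw(params, zero_load, p_min_mmhg=0.0,
                          p_max_mmhg=record.sbp + 15.0, lam_z=config.lam_z)
    p_in = scale_waveform(wiggers_template, record.sbp, record.dbp,
                          period=config.period_s)
    ctx = FlowContext(law, blood, n_cycles=config.flow_cycles,
                      rtol=config.flow_rtol, max_nodes=config.flow_max_nodes)
    if measurements.doppler_inlet_velocity is None:
        flags.append("uncalibrated_outlet")
        p_out = p_in.shifted(0.0)
    else:
        p_out, res_out = calibrate_outlet(
            p_in, measurements.doppler_inlet_velocity, ctx,
            offset_bounds=config.offset_bounds, tol=config.calibration_tol)
        calib["outlet"] = _calib_record(res_out)

    # 4. final forward solves and metric extraction
    state_dia = solve_vessel(params, zero_load, dbp_kpa, config.lam_z)
    state_sys = solve_vessel(params, zero_load, sbp_kpa, config.lam_z)
    mean_disp, max_disp = displacement_metrics(state_dia, state_sys)
    flow = solve_flow(law, blood, p_in, p_out, n_cycles=config.flow_cycles,
                      rtol=config.flow_rtol, max_nodes=config.flow_max_nodes)
    phases = flow.velocities_at_phases()

    metrics = {
        "inlet_velocity/diastolic": phases["inlet_velocity_diastolic"],
        "inlet_velocity/systolic": phases["inlet_velocity_systolic"],
        "mean_velocity/diastolic": phases["mean_velocity_diastolic"],
        "mean_velocity/systolic": phases["mean_velocity_systolic"],
        "max_displacement/systolic": max_disp,
        "mean_displacement/systolic": mean_disp,
        "max_stress_p1/diastolic": state_dia.max_stress_P1,
        "max_stress_p1/systolic": state_sys.max_stress_P1,
        "mean_stress_p1/diastolic": state_dia.mean_stress_P1,
        "mean_stress_p1/systolic": state_sys.mean_stress_P1,
    }
    return PatientResult(record.id, record.group, metrics, calib, flags)


def results_to_metrics_frame(results) -> pd.DataFrame:
    """Long-form (metric, phase, group, value) frame from PatientResults."""
    rows = []
    for res in results:
        for key, value in res.metrics.items():
            metric, phase = key.split("/")
            rows.append(dict(patient_id=res.patient_id, metric=metric,
                             phase=phase, group=res.group, value=value))
    return pd.DataFrame(rows)


def run_cohort(records, geometries, measurements, config: RunConfig = RunConfig(),
               output_dir=None):
    """Run the full pipeline over a cohort and compare the groups.

    ``geometries`` and ``measurements`` map patient id to the diastolic
    geometry and measurement set.  Failing patients are reported, not fatal;
    fewer than 2 usable patients in a group aborts.  Returns a dict bundle
    with per-patient results, the metric frame, result tables, comparisons
    and an error report; writes CSV/JSON/text outputs when ``output_dir``
    is given.
    """
    if any(r.group is None for r in records):
        records = split_by_zscore(records)
    results, errors = [], []
    for rec in records:
        try:
            results.append(run_patient(rec, geometries[rec.id],
                                       measurements[rec.id], config))
        except (AortamechError, KeyError) as err:
            errors.append({"patient_id": rec.id, "stage": type(err).__name__,
                           "message": str(err)})
    usable = {g: sum(1 for r in results if r.group == g)
              for g in ("nondilated", "dilated")}
    if min(usable.values()) < 2:
        raise ConfigurationError(
            f"fewer than 2 usable patients per group: {usable}; "
            f"errors: {errors}")

    frame = results_to_metrics_frame(results)
    tables, comparisons, incomplete = build_results_tables(
        frame, alpha=config.alpha, strict_normality=config.strict_normality)
    sex_p = compare_sex(
        [r.sex for r in records if r.group == "nondilated"],
        [r.sex for r in records if r.group == "dilated"])

    bundle = {
        "results": results,
        "metrics": frame,
        "tables": tables,
        "comparisons": comparisons,
        "incomplete": incomplete,
        "errors": errors,
        "sex_fisher_p": sex_p,
        "config": config,
    }
    if output_dir is not None:
        _write_bundle(bundle, Path(output_dir), config)
    return bundle


def _write_bundle(bundle, outdir: Path, config: RunConfig):
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "outputs": []}
    for res in bundle["results"]:
        p = outdir / f"patient_{res.patient_id}.json"
        res.to_json(p)
        manifest["outputs"].append(p.name)
    bundle["metrics"].to_csv(outdir / "metrics.csv", index=False)
    manifest["outputs"].append("metrics.csv")
    for (metric, phase), df in bundle["tables"].items():
        name = f"table_{metric}_{phase}.csv"
        df.to_csv(outdir / name)
        manifest["outputs"].append(name)
    (outdir / "tables.txt").write_text(render_table_text(bundle["tables"]))
    comp = {
        f"{m}/{ph}": {
            "test_used": c.test_used, "t_statistic": c.t_statistic,
            "p_value": c.p_value, "levene_p": c.levene_p,
            "shapiro_p": list(c.shapiro_p),
            "means": list(c.group_means), "sds": list(c.group_sds),
        }
        for (m, ph), c in bundle["comparisons"].items()
    }
    comp["sex_fisher_p"] = bundle["sex_fisher_p"]
    (outdir / "comparisons.json").write_text(json.dumps(comp, indent=2,
                                                        sort_keys=True))
    config.to_yaml(outdir / "config.yaml")
    manifest["outputs"] += ["tables.txt", "comparisons.json", "config.yaml"]
    if bundle["errors"]:
        (outdir / "errors.json").write_text(json.dumps(bundle["errors"],
                                                       indent=2))
        manifest["outputs"].append("errors.json")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
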