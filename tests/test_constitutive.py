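"""Constitutive model: invariants, energy, stress differences, fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import pearsonr, special_ortho_group

from aortamech.constitutive import (
    Kinematics,
    MaterialParams,
    StressState,
    check_uniaxial_stability,
    fit_baseline_params,
    scale_params,
    strain_energy,
    strain_energy_incompressible,
    stress_difference,
    strain_invariants,
    uniaxial_stress,
)
from aortamech.errors import (
    DegenerateDataError,
    InvalidKinematicsError,
    OutOfRangeDeformationError,
)

E1 = np.array([1.0, 0.0, 0.0])


class TestStrainInvariants:
    def test_undeformed_state(self):
        assert strain_invariants(np.eye(3), E1) == (3.0, 3.0, 1.0)

    def test_diagonal_stretch_against_index_summation(self):
        C = np.diag([1.44, 1.0, 1.0 / 1.44])
        I1, I2, I4 = strain_invariants(C, E1)
        # brute-force index summation of the printed formulas
        I1_ref = sum(C[i, i] for i in range(3))
        I2_ref = 0.5 * (I1_ref**2 - sum(C[i, j] ** 2 for i in range(3)
                                        for j in range(3)))
        assert I1 == pytest.approx(I1_ref, abs=1e-14)
        assert I2 == pytest.approx(I2_ref, abs=1e-14)
        assert I1 == pytest.approx(3.134444444, abs=1e-9)
        assert I4 == pytest.approx(1.44, abs=1e-14)

    def test_agrees_with_eigenvalue_formulas_for_unimodular_F(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            X = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
            X /= np.cbrt(np.linalg.det(X))
            C = X.T @ X
            lam2 = np.linalg.eigvalsh(C)
            I1, I2, _ = strain_invariants(C, E1)
            assert I1 == pytest.approx(lam2.sum(), rel=1e-12)
            I2_eig = (lam2[0] * lam2[1] + lam2[0] * lam2[2]
                      + lam2[1] * lam2[2])
            assert I2 == pytest.approx(I2_eig, rel=1e-10)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(7)
        X = np.diag([1.2, 0.9, 1.0 / 1.08])
        C = X.T @ X
        nf = np.array([0.0, 1.0, 0.0])
        ref = strain_invariants(C, nf)
        for _ in range(10):
            R = special_ortho_group.rvs(3, random_state=rng)
            got = strain_invariants(R @ C @ R.T, R @ nf)
            assert got == pytest.approx(ref, rel=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidKinematicsError):
            strain_invariants(np.diag([1.0, -0.5, 1.0]), E1)
        with pytest.raises(InvalidKinematicsError):
            strain_invariants(np.arange(9.0).reshape(3, 3), E1)


class TestStrainEnergy:
    def test_zero_at_reference(self, baseline):
        assert strain_energy(baseline, np.eye(3)) == 0.0

    def test_term_by_term_oracle(self, baseline):
        C = np.diag([1.44, 1.0, 1.0 / 1.44])
        # fiber along the stretched axis
        p = MaterialParams(baseline.c1, baseline.c2, baseline.D1, baseline.D2,
                           baseline.K1, baseline.K2, fiber_direction=E1)
        I1, I2, I4 = strain_invariants(C, E1)
        expected = (p.c1 * (I1 - 3) + p.c2 * (I2 - 3)
                    + p.D1 * (math.exp(p.D2 * (I1 - 3)) - 1)
                    + p.K1 / p.K2 * (math.exp(p.K2 * (I4 - 1) ** 2) - 1))
        assert strain_energy(p, C) == pytest.approx(expected, rel=1e-14)

    def test_linear_in_stress_dimensioned_constants(self, baseline):
        C = np.diag([1.21, 1.0, 1.0 / 1.21])
        for r in (0.5, 2.0, 7.3):
            assert strain_energy(scale_params(baseline, r), C) == pytest.approx(
                r * strain_energy(baseline, C), rel=1e-14)

    def test_overflow_reported(self, baseline):
        with pytest.raises(OutOfRangeDeformationError):
            strain_energy(baseline, np.diag([400.0, 1.0, 1.0 / 400.0]))


class TestStressDifference:
    def test_zero_at_reference(self, baseline):
        assert stress_difference(baseline, 1.0, 1.0) == (0.0, 0.0)

    def test_finite_difference_oracle_over_grid(self, baseline):
        h = 1e-6
        for lt in np.linspace(0.8, 1.3, 11):
            for lz in np.linspace(0.8, 1.3, 11):
                d_t, d_z = stress_difference(baseline, lt, lz)
                fd_t = lt * (strain_energy_incompressible(baseline, lt + h, lz)
                             - strain_energy_incompressible(baseline, lt - h, lz)) / (2 * h)
                fd_z = lz * (strain_energy_incompressible(baseline, lt, lz + h)
                             - strain_energy_incompressible(baseline, lt, lz - h)) / (2 * h)
                scale = max(abs(fd_t), abs(fd_z), 1.0)
                assert abs(d_t - fd_t) / scale < 1e-5
                assert abs(d_z - fd_z) / scale < 1e-5

    def test_scales_linearly(self, baseline):
        d = stress_difference(baseline, 1.1, 1.05)
        d3 = stress_difference(scale_params(baseline, 3.0), 1.1, 1.05)
        assert d3 == pytest.approx(tuple(3 * x for x in d), rel=1e-14)

    def test_nonpositive_stretch_rejected(self, baseline):
        with pytest.raises(InvalidKinematicsError):
            stress_difference(baseline, -1.0, 1.0)


class TestScaleParams:
    def test_identity_and_arithmetic(self, baseline):
        assert scale_params(baseline, 1.0) == baseline
        doubled = scale_params(baseline, 2.0)
        assert doubled.c1 == pytest.approx(-1050.32)
        assert doubled.K1 == pytest.approx(66.8)
        assert doubled.D2 == baseline.D2 and doubled.K2 == baseline.K2

    def test_nonpositive_ratio_rejected(self, baseline):
        with pytest.raises(ValueError):
            scale_params(baseline, 0.0)


class TestUniaxialFit:
    def test_noise_free_recovery(self, baseline):
        lam = np.linspace(1.02, 1.25, 12)
        p_true = MaterialParams(baseline.c1, baseline.c2, baseline.D1,
                                baseline.D2, baseline.K1, baseline.K2)
        data = np.column_stack([lam, uniaxial_stress(p_true, lam)])
        init = scale_params(p_true, 1.3)
        fitted, r2 = fit_baseline_params(data, init)
        assert r2 > 0.999
        for name in ("c1", "c2", "D1", "K1"):
            assert getattr(fitted, name) == pytest.approx(
                getattr(p_true, name), rel=0.01)

    def test_constant_stress_is_degenerate(self, baseline):
        data = np.column_stack([np.linspace(1.0, 1.2, 8), np.zeros(8)])
        with pytest.raises(DegenerateDataError):
            fit_baseline_params(data, baseline)

    def test_multiplicative_noise_leaves_uncorrelated_residuals(self, baseline):
        rng = np.random.default_rng(3)
        lam = np.linspace(1.02, 1.28, 20)
        sig = uniaxial_stress(baseline, lam) * (1 + 0.1 * rng.standard_normal(20))
        fitted, r2 = fit_baseline_params(np.column_stack([lam, sig]), baseline)
        assert r2 < 1.0
        resid = uniaxial_stress(fitted, lam) - sig
        assert abs(pearsonr(lam, resid).statistic) < 0.5


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    lam_t=st.floats(0.85, 1.25),
    lam_z=st.floats(0.9, 1.15),
    ratio=st.floats(0.1, 10.0),
)
def test_stress_difference_properties_hold_over_parameter_space(lam_t, lam_z,
                                                                ratio):
    """For arbitrary admissible states: stress differences scale linearly
    with the stiffness ratio and match finite differences of the energy."""
    p = MaterialParams.human_aorta_baseline()
    d = stress_difference(p, lam_t, lam_z)
    d_scaled = stress_difference(scale_params(p, ratio), lam_t, lam_z)
    assert d_scaled == pytest.approx((ratio * d[0], ratio * d[1]), rel=1e-12)
    h = 1e-6
    fd_t = lam_t * (strain_energy_incompressible(p, lam_t + h, lam_z)
                    - strain_energy_incompressible(p, lam_t - h, lam_z)) / (2 * h)
    assert d[0] == pytest.approx(fd_t, rel=1e-4, abs=1e-4)


def test_stability_check_warns_on_softening_set():
    unstable = MaterialParams(c1=-500.0, c2=10.0, D1=1.0, D2=0.1,
                              K1=0.1, K2=0.1)
    with pytest.warns(RuntimeWarning):
        assert check_uniaxial_stability(unstable) is False


def test_kinematics_and_stress_state_containers():
    X = np.diag([1.2, 1.0, 1.0 / 1.2])
    kin = Kinematics.from_deformation_gradient(X)
    assert kin.invariants[0] == pytest.approx(np.trace(X.T @ X))
    assert np.allclose(kin.green_strain, 0.5 * (X.T @ X - np.eye(3)))
    s = StressState(np.diag([5.0, -2.0, 1.0]), lagrange_pressure=1.0)
    assert s.stress_P1 == 5.0
    assert np.allclose(s.principal_stresses, [5.0, 1.0, -2.0])


def test_params_serialization_roundtrip(tmp_path, baseline):
    path = tmp_path / "params.yaml"
    baseline.to_yaml(path)
    assert MaterialParams.from_yaml(path) == baseline
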