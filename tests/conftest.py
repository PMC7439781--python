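import numpy as np
import pytest

from aortamech.constitutive import MaterialParams
from aortamech.hemodynamics import (
    BloodProperties,
    PressureAreaLaw,
    PressureWaveform,
    scale_waveform,
    wiggers_template,
)
from aortamech.vessel_mechanics import VesselGeometry


@pytest.fixture(scope="session")
def baseline():
    return MaterialParams.human_aorta_baseline()


@pytest.fixture(scope="session")
def cylinder():
    return VesselGeometry.uniform_cylinder(12.0, 60.0, n_rings=11)


@pytest.fixture(scope="session")
def tapered():
    return VesselGeometry.tapered(13.0, 11.5, 60.0, n_rings=13)


@pytest.fixture(scope="session")
def blood():
    return BloodProperties(5.0)


@pytest.fixture(scope="session")
def waveform():
    return scale_waveform(wiggers_template, 108.0, 62.0)


@pytest.fixture(scope="session")
def tube_law(baseline, cylinder):
    return PressureAreaLaw(baseline, cylinder, p_min_mmhg=0.0, p_max_mmhg=125.0)


@pytest.fixture(scope="session")
def constant_waveforms():
    """Constant 90 / 85 mmHg inlet/outlet traces (steady-flow oracle)."""
    t = np.linspace(0.0, 0.8, 201)
    p_in = PressureWaveform(t, np.full(201, 90.0), 90.0, 90.0)
    p_out = PressureWaveform(t, np.full(201, 85.0), 85.0, 85.0)
    return p_in, p_out
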