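"""Centralized unit conversions.

Internal unit system: g / mm / s.  In this system pressure and stress come
out in Pa (1 Pa = 1 g mm^-1 s^-2), so

* structural stresses are carried in kPa,
* flow pressures in Pa,
* lengths in mm, flows in mm^3/s, velocities in mm/s,
* dynamic viscosity in Pa s (1 cPoise = 1e-3 Pa s),
* fluid density 1 g/cm^3 = 1e-3 g/mm^3.
"""

MMHG_TO_KPA = 0.133322
KPA_TO_MMHG = 1.0 / MMHG_TO_KPA

MMHG_TO_PA = MMHG_TO_KPA * 1e3
KPA_TO_PA = 1e3

CPOISE_TO_PA_S = 1e-3

#: blood density, g/mm^3 (1 g/cm^3)
BLOOD_DENSITY_G_PER_MM3 = 1e-3


def mmhg_to_kpa(p):
    return p * MMHG_TO_KPA


def kpa_to_mmhg(p):
    return p * KPA_TO_MMHG


def mmhg_to_pa(p):
    return p * MMHG_TO_PA
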