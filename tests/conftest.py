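"""Shared fixtures: the reference characterization results of the
seven-formulation ointment study used as ground truth throughout."""

import numpy as np
import pytest

from semisolid.texture import TPAProfile

#: formulation -> (a, b, R^2, AUC over [298, 798] g, i(S) vs F-1)
SPREAD_FITS = {
    "F-1": (20.899, -92.743, 0.943, 19281.4, None),
    "F-2": (21.851, -93.754, 0.933, 21786.7, 1.130),
    "F-3": (19.898, -82.552, 0.931, 21246.4, 1.102),
    "F-4": (16.791, -67.144, 0.942, 19111.5, 0.991),
    "F-5": (20.814, -89.592, 0.957, 20523.5, 1.064),
    "F-6": (20.474, -86.238, 0.937, 21215.6, 1.100),
    "F-7": (17.752, -80.112, 0.966, 15660.8, 0.812),
}

#: formulation -> temperature -> mean viscosity [mPa*s] at (300, 700, 1100) 1/s
STEP_VISCOSITIES = {
    "F-1": {25.0: (1907, 1257, 741), 32.0: (754, 528, 471)},
    "F-7": {25.0: (2071, 1364, 798), 32.0: (1853, 1236, 782)},
}

#: the four texture profiles of the reference study
TPA_ROWS = {
    "F-1": TPAProfile(0.419, 1.107, 0.567, 1.130, -0.130),
    "F-2": TPAProfile(0.205, 0.885, 0.325, 0.950, -0.053),
    "F-3": TPAProfile(0.227, 0.869, 0.400, 0.947, -0.059),
    "F-6": TPAProfile(0.801, 0.360, 1.683, 0.787, -0.260),
}

#: formulation -> (Higuchi rate [mg/cm^2/min^0.5], SD, loaded dose [mg])
HIGUCHI_RATES = {
    "F-5": (0.41, 0.02, 15.0),
    "F-6": (0.48, 0.05, 20.0),
    "F-7": (0.52, 0.03, 25.0),
}

#: UV calibration line at 276.5 nm: absorbance = slope*conc + intercept
CALIBRATION = (0.5831, -0.0169)
CALIBRATION_CONCS = (0.1, 0.2, 0.4, 0.5, 0.6, 0.8, 1.0)

RELEASE_TIMES = (15.0, 30.0, 60.0, 90.0, 120.0, 150.0)
VESSEL = dict(vessel_volume_ml=50.0, sample_volume_ml=3.0, orifice_area_cm2=3.8)


@pytest.fixture(scope="session")
def spread_fits():
    return SPREAD_FITS


@pytest.fixture(scope="session")
def tpa_rows():
    return TPA_ROWS


@pytest.fixture(scope="session")
def higuchi_rates():
    return HIGUCHI_RATES


@pytest.fixture(scope="session")
def calibration():
    from semisolid.release import CalibrationResults

    return CalibrationResults(
        slope=CALIBRATION[0], intercept=CALIBRATION[1], r_squared=1.0
    )
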