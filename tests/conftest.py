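"""Shared fixtures.

The calibrated observer fixture runs the actual calibration operation once
per session (root-finding on the utricular weight against the 20 deg roll /
2 G steady-state target) so acceptance tests exercise the calibration path
rather than trusting the shipped default weight.
"""

import pytest

from gravitilt import ObserverParams, TiltCondition, calibrate_utricular_weight

#: Steady-state target for the calibration case: the modified-shear
#: prediction at 20 deg roll / 2 G with the default coefficients, standing in
#: for the unpublished raw datum.
CALIBRATION_TARGET_DEG = 27.55
CALIBRATION_CONDITION = TiltCondition("roll", 20.0, 2.0)


@pytest.fixture(scope="session")
def default_params() -> ObserverParams:
    return ObserverParams()


@pytest.fixture(scope="session")
def calibrated_params(default_params) -> ObserverParams:
    return calibrate_utricular_weight(
        CALIBRATION_CONDITION, CALIBRATION_TARGET_DEG, default_params)
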