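import pytest
from hypothesis import HealthCheck, settings

import crcscreen as c
from crcscreen.engine import calibrate

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def base_params():
    return c.base_case()


@pytest.fixture(scope="session")
def calibration(base_params):
    """Default calibration to the reference no-screening cancer burden."""
    return calibrate(base_params)


@pytest.fixture(scope="session")
def calibrated_params(calibration):
    return calibration.params
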