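import pytest

from accelcal import default_calibration_config, default_validation_config
from accelcal.pipeline import run_calibration, run_study


@pytest.fixture(scope="session")
def small_config():
    """A complete calibration study at reduced cohort size and sampling
    rate so the whole pipeline stays fast; the protocol (7 bouts, 5
    locations) is the full one."""
    return default_calibration_config(seed=11, n_participants=3, sampling_rate=20)


@pytest.fixture(scope="session")
def small_study(small_config):
    table, join, steady = run_study(small_config)
    return table, join, steady


@pytest.fixture(scope="session")
def small_calibration(small_config):
    return run_calibration(small_config)


@pytest.fixture(scope="session")
def small_validation_config():
    return default_validation_config(seed=12, n_participants=3, sampling_rate=20)
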