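import numpy as np
import pytest

from footclear import (
    PROFILES,
    SensorErrorModel,
    fit_calibration,
    make_trajectory,
    synthesize_imu,
    synthesize_static_set,
)

FS = 200.0


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def truth_normal():
    """Default 5-stride walking trial at 200 Hz."""
    return make_trajectory(PROFILES["normal"], FS)


@pytest.fixture(scope="session")
def ideal_recording(truth_normal):
    """The default walk seen by a perfect sensor (no errors, no noise)."""
    return synthesize_imu(truth_normal, SensorErrorModel.ideal())


@pytest.fixture(scope="session")
def default_recording(truth_normal):
    """The default walk with the full default error model, seed 1."""
    return synthesize_imu(truth_normal, SensorErrorModel(seed=1))


@pytest.fixture(scope="session")
def default_model():
    """Calibration fitted once from a synthetic 30-orientation static set."""
    err = SensorErrorModel(seed=1)
    return fit_calibration(synthesize_static_set(err, 30, seed=1001))
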