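import numpy as np
import pytest

from imukin.calibration import average_orientation, calibrate
from imukin.fusion import FilterConfig, run_filter
from imukin.io import resample_orientations
from imukin.model import build_default_model
from imukin.synthetic import TrajectoryConfig, generate_trial


@pytest.fixture(scope="session")
def model():
    return build_default_model()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def walk_trial():
    """20-s zero-noise walking trial at 100 Hz (5-s standing calibration)."""
    return generate_trial(
        config=TrajectoryConfig(duration_s=20.0, rate_hz=100.0, activity="walk"),
        seed=7,
    )


@pytest.fixture(scope="session")
def walk_fused(walk_trial):
    cfg = FilterConfig()
    return {s: run_filter(ser, cfg) for s, ser in walk_trial.imu.items()}


@pytest.fixture(scope="session")
def walk_registration(walk_trial, walk_fused):
    measured = {s: average_orientation(ser.slice(0.0, 5.0)) for s, ser in walk_fused.items()}
    return calibrate(walk_trial.model, None, measured)


@pytest.fixture(scope="session")
def walk_orientations_20hz(walk_trial, walk_fused):
    t_ik = np.arange(0.0, walk_trial.t[-1] + 1e-9, 0.05)
    return t_ik, {s: resample_orientations(ser, t_ik) for s, ser in walk_fused.items()}
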