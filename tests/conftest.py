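import numpy as np
import pytest

from imupose.core import FrameConvention, SensorNoiseModel, TrackerStates, TRACKER_IDS
from imupose.skeleton import CalibrationResult, fk_batch, skeleton_from_height, tracker_world_pose


@pytest.fixture(scope="session")
def frame():
    return FrameConvention()


@pytest.fixture(scope="session")
def noiseless():
    return SensorNoiseModel(accel_noise_density=0.0, gyro_noise_density=0.0)


@pytest.fixture(scope="session")
def sk():
    return skeleton_from_height(1580.0)


@pytest.fixture(scope="session")
def cal():
    return CalibrationResult.identity()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def perfect_states_from_trace(trace, sk):
    """Tracker state sequences read straight off forward kinematics."""
    fk = fk_batch(sk, trace.joint_rotvecs())
    out = {}
    n = len(trace)
    for tr in TRACKER_IDS:
        pos_mm, q = tracker_world_pose(sk, fk, tr)
        out[tr] = TrackerStates(t=trace.t, q=q, v=np.zeros((n, 3)), d=pos_mm / 1000.0,
                                tracker_id=tr)
    return out
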