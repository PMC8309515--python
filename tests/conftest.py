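import dataclasses

import numpy as np
import pytest

from imukin import prep, synthetic


@pytest.fixture(scope="session")
def profile() -> synthetic.ParticipantProfile:
    """One deterministic participant."""
    return synthetic.make_cohort(1, 42)[0]


@pytest.fixture(scope="session")
def quiet_profile(profile) -> synthetic.ParticipantProfile:
    """Same participant with sensor noise and stride jitter switched off."""
    return dataclasses.replace(profile, noise_sd_accel=0.0, noise_sd_gyro=0.0,
                               stride_jitter_cv=0.0)


@pytest.fixture(scope="session")
def smoke_plan() -> prep.SegmentationPlan:
    """Segmentation for 30 s sessions: 10 s head, one 16 s segment, 4 s tail."""
    return prep.SegmentationPlan(buffer_head=10.0, buffer_tail=4.0,
                                 split=(16.0,), selected_segment=0)


@pytest.fixture(scope="session")
def quiet_session(quiet_profile) -> synthetic.Session:
    """A 30 s noise-free level-ground session."""
    return synthetic.Session(*synthetic.simulate_session(
        quiet_profile, synthetic.LEVEL_GROUND, 2.5, 30.0, seed=7))


def gait_slice(kin: synthetic.KinematicsRecording, joint: str) -> np.ndarray:
    """The running part of a kinematics trace (preamble and stomps excluded)."""
    trace = kin.knee_flexion if joint == "knee" else kin.hip_flexion
    return trace[kin.t >= synthetic.PREAMBLE_S + 1.0]
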