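"""Shared fixtures: random rotations and small gait/simulation fixtures."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from imu2seg.body_model import I2SPose, SegmentClass, default_base_alignments
from imu2seg.synthetic_gait import (
    GaitParams,
    SubjectAnthropometrics,
    default_i2s_positions,
    generate_walk,
    sample_subject,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def random_rotations(rng):
    """1000 uniformly random rotation matrices."""
    return Rotation.random(1000, rng=np.random.default_rng(7)).as_matrix()


@pytest.fixture(scope="session")
def subject():
    return sample_subject(1)


@pytest.fixture(scope="session")
def short_walk(subject):
    """A 10-second walking take from one subject (600 frames at 60 Hz)."""
    anthro, params = subject
    from dataclasses import replace
    return generate_walk(anthro, replace(params, duration_s=10.0))


@pytest.fixture(scope="session")
def static_pose():
    """A motionless skeleton: every amplitude and the stride set to zero."""
    anthro = SubjectAnthropometrics(height=1.75)
    params = GaitParams(stride_length=0.0, hip_amplitude_deg=0.0,
                        knee_peak_deg=0.0, ankle_amplitude_deg=0.0,
                        pelvis_vertical_amp_m=0.0, pelvis_lateral_amp_m=0.0,
                        asymmetry_jitter=0.0, duration_s=5.0)
    return anthro, params, generate_walk(anthro, params)


@pytest.fixture(scope="session")
def base_i2s():
    """Default mounting poses at segment midpoints for a 1.75 m subject."""
    anthro = SubjectAnthropometrics(height=1.75)
    base = default_base_alignments()
    pos = default_i2s_positions(anthro)
    return {seg: I2SPose(base[seg], pos[seg]) for seg in SegmentClass}
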