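"""Procedural multi-subject walking kinematics for the 7-segment lower body.

This module emulates, at desk scale, the kind of 3D kinematics corpora used
to train IMU assignment/alignment models: many subjects walking back and
forth or in an eight-shape, each with their own stature, cadence, stride and
gait-pattern amplitudes.  It is a *stand-in* for recorded motion capture:
joint angles are low-order Fourier approximations of sagittal-plane gait
curves, not measured trajectories, and there is no ground-contact or
soft-tissue model.  What it does reproduce is the structure the downstream
networks exploit — strictly periodic hip/knee/ankle patterns, left/right
phase opposition (half a gait cycle), pelvis translation with vertical and
lateral oscillation, and per-subject anthropometric and cadence variation.

Conventions: global frame z-up, 60 Hz.  Segment frames have x anterior and
z longitudinal (pointing proximally) for the legs, x anterior and z up for
the feet.  Flexion angles are in degrees.  Segment lengths are standard
anthropometric fractions of body height (thigh 0.245, shank 0.246, foot
length 0.152, pelvis width 0.191).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from imu2seg.body_model import SegmentClass, SkeletonPose

__all__ = [
    "SubjectAnthropometrics",
    "GaitParams",
    "sample_subject",
    "generate_walk",
    "joint_angle_series",
    "kinematic_chain_gaps",
    "SAMPLE_RATE_HZ",
]

SAMPLE_RATE_HZ = 60.0

# segment lengths as fractions of stature (standard anthropometric tables)
_THIGH_FRAC = 0.245
_SHANK_FRAC = 0.246
_FOOT_FRAC = 0.152
_PELVIS_W_FRAC = 0.191
_ANKLE_H_FRAC = 0.039


@dataclass(frozen=True)
class SubjectAnthropometrics:
    """Stature-derived body dimensions (meters)."""

    height: float

    def __post_init__(self) -> None:
        if not 1.4 <= self.height <= 2.1:
            raise ValueError("height must be within [1.4, 2.1] m")

    @property
    def thigh(self) -> float:
        return _THIGH_FRAC * self.height

    @property
    def shank(self) -> float:
        return _SHANK_FRAC * self.height

    @property
    def foot(self) -> float:
        return _FOOT_FRAC * self.height

    @property
    def pelvis_width(self) -> float:
        return _PELVIS_W_FRAC * self.height

    @property
    def ankle_height(self) -> float:
        return _ANKLE_H_FRAC * self.height


@dataclass(frozen=True)
class GaitParams:
    """Gait-pattern parameters of one walking take.

    Angles are amplitudes in degrees, oscillations in meters, cadence in
    steps/min.  ``asymmetry_jitter`` is the fractional perturbation applied
    to the right leg's amplitudes and to its half-cycle phase offset.
    Defaults are typical self-selected-speed adult walking.
    """

    cadence: float = 112.0
    stride_length: float = 1.35
    duration_s: float = 30.0
    hip_amplitude_deg: float = 22.0
    knee_peak_deg: float = 62.0
    ankle_amplitude_deg: float = 48.0
    pelvis_vertical_amp_m: float = 0.030
    pelvis_lateral_amp_m: float = 0.035
    asymmetry_jitter: float = 0.02
    path: str = "eight"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cadence <= 0:
            raise ValueError("cadence must be positive")
        for a in (self.hip_amplitude_deg, self.knee_peak_deg,
                  self.ankle_amplitude_deg, self.pelvis_vertical_amp_m,
                  self.pelvis_lateral_amp_m, self.stride_length,
                  self.asymmetry_jitter):
            if a < 0:
                raise ValueError("amplitudes must be non-negative")
        if self.path not in ("straight", "eight"):
            raise ValueError("path must be 'straight' or 'eight'")

    @property
    def stride_freq_hz(self) -> float:
        """Gait-cycle (stride = two steps) frequency."""
        return self.cadence / 120.0


def sample_subject(seed: int) -> tuple[SubjectAnthropometrics, GaitParams]:
    """Draw one subject's anthropometrics and gait parameters.

    All draws are uniform over ranges typical of healthy adult walking;
    stride length scales with stature.  The same seed always returns the
    same subject.
    """
    rng = np.random.default_rng(seed)
    height = rng.uniform(1.55, 1.95)
    params = GaitParams(
        cadence=rng.uniform(96.0, 126.0),
        stride_length=rng.uniform(1.15, 1.50) * (height / 1.75),
        hip_amplitude_deg=rng.uniform(18.0, 26.0),
        knee_peak_deg=rng.uniform(55.0, 68.0),
        ankle_amplitude_deg=rng.uniform(40.0, 55.0),
        pelvis_vertical_amp_m=rng.uniform(0.020, 0.040),
        pelvis_lateral_amp_m=rng.uniform(0.020, 0.050),
        asymmetry_jitter=rng.uniform(0.0, 0.03),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return SubjectAnthropometrics(height=height), params


# ----------------------------------------------------------------------
# joint-angle patterns (truncated Fourier series in the stride phase)
# ----------------------------------------------------------------------

def _knee_pattern(phi: np.ndarray) -> np.ndarray:
    """Non-negative knee flexion shape normalized to peak 1.

    Two harmonics of the stride phase: a dominant swing-phase flexion peak
    plus a smaller stance-phase flexion wave.
    """
    raw = 0.35 * (1.0 - np.cos(phi - 0.4)) + 0.65 * (1.0 - np.cos(2.0 * phi + 0.9))
    return raw / np.max(raw) if np.max(raw) > 0 else raw


def joint_angle_series(params: GaitParams, phi: np.ndarray,
                       amp_scale: float = 1.0) -> dict:
    """Hip, knee and foot-pitch angle series (degrees) at stride phase ``phi``.

    ``amp_scale`` applies the per-leg asymmetry factor.  All curves are
    strictly periodic in ``phi`` with period 2*pi, so shifting the phase by
    pi yields the opposite leg's pattern.
    """
    hip = amp_scale * params.hip_amplitude_deg * np.sin(phi)
    knee = amp_scale * params.knee_peak_deg * _knee_pattern(phi)
    # foot pitch: dominant stride-frequency wave plus a push-off harmonic.
    # The summed excursion (~1.4x the amplitude parameter) and its rate
    # reflect that the foot shows the largest angular velocities in gait.
    foot = amp_scale * params.ankle_amplitude_deg * (
        np.sin(phi + 0.7) + 0.5 * np.sin(2.0 * phi + 2.1))
    return {"hip": hip, "knee": knee, "foot": foot}


# ----------------------------------------------------------------------
# walking path
# ----------------------------------------------------------------------

def _path_xy(params: GaitParams, n: int, speed: float) -> tuple[np.ndarray, np.ndarray]:
    """Constant-speed positions and headings along the configured path.

    'straight' is a strongly elongated oval (back and forth within about
    5 x 1 m with smooth turnarounds); 'eight' is a figure-eight inside a
    5 x 5 m area.  Returns (positions (n, 2), heading (n,) radians).
    """
    if speed <= 0:
        return np.zeros((n, 2)), np.zeros(n)
    # dense parameterization, then arc-length reparameterization
    total_needed = speed * n / SAMPLE_RATE_HZ
    if params.path == "straight":
        def xy(u):
            return np.stack([2.5 * np.cos(u), 0.5 * np.sin(u)], axis=-1)
        lap_len_guess = 2 * np.pi * 1.8
    else:  # eight-shape (Gerono lemniscate)
        def xy(u):
            return np.stack([2.5 * np.sin(2.0 * u), 2.5 * np.sin(u)], axis=-1)
        lap_len_guess = 14.0
    laps = total_needed / lap_len_guess + 2.0
    u_dense = np.linspace(0.0, 2.0 * np.pi * laps, int(4000 * laps))
    p_dense = xy(u_dense)
    seglen = np.linalg.norm(np.diff(p_dense, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    s_t = speed * np.arange(n) / SAMPLE_RATE_HZ
    u_t = np.interp(s_t, arclen, u_dense)
    pos = xy(u_t)
    d = xy(u_t + 1e-5) - xy(u_t - 1e-5)
    heading = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
    return pos, heading


# ----------------------------------------------------------------------
# forward kinematics
# ----------------------------------------------------------------------

def _batch_rot_y(angles_deg: np.ndarray) -> np.ndarray:
    a = np.atleast_1d(np.asarray(angles_deg, float))
    return Rotation.from_euler("y", a[:, None], degrees=True).as_matrix()


def _leg_chain(R_pelvis, hip_pos, angles, anthro):
    """Global poses of thigh, shank, foot for one leg (vectorized over time)."""
    Ry = _batch_rot_y
    # flexion about -y moves the distal (-z) end anteriorly (+x)
    R_thigh = R_pelvis @ Ry(-angles["hip"])
    knee = hip_pos + np.einsum("tij,j->ti", R_thigh,
                               np.array([0.0, 0.0, -anthro.thigh]))
    R_shank = R_thigh @ Ry(angles["knee"])
    ankle = knee + np.einsum("tij,j->ti", R_shank,
                             np.array([0.0, 0.0, -anthro.shank]))
    return R_thigh, knee, R_shank, ankle


def generate_walk(anthro: SubjectAnthropometrics,
                  params: GaitParams) -> SkeletonPose:
    """Generate one walking take as global poses of all seven segments.

    The pelvis translates along the configured path at the speed implied by
    stride length and cadence, oscillating vertically at step frequency and
    laterally at stride frequency, with small roll/pitch waves.  Leg joint
    angles follow the truncated-Fourier patterns of
    :func:`joint_angle_series`, the right leg offset by half a gait cycle
    (plus the seeded asymmetry jitter).  Forward kinematics then yields
    consistent segment orientations and origins: thighs hang from the hip
    points, shanks from the knees, feet sit at the ankles.
    """
    n = int(round(params.duration_s * SAMPLE_RATE_HZ))
    t = np.arange(n) / SAMPLE_RATE_HZ
    f = params.stride_freq_hz
    phi = 2.0 * np.pi * f * t

    rng = np.random.default_rng(params.seed)
    j = params.asymmetry_jitter
    right_phase = np.pi * (1.0 + rng.uniform(-j, j))
    right_scale = 1.0 + rng.uniform(-j, j)

    speed = params.stride_length * f
    path_pos, heading = _path_xy(params, n, speed)

    # pelvis pose
    hip_height = (anthro.thigh + anthro.shank + anthro.ankle_height) * 0.97
    roll = 2.0 * np.sin(phi) * (params.pelvis_lateral_amp_m / 0.035)
    pitch = 1.5 * np.sin(2.0 * phi + 0.5) * (params.pelvis_vertical_amp_m / 0.030)
    R_pelvis = Rotation.from_euler(
        "ZYX", np.stack([np.degrees(heading), pitch, roll], axis=1),
        degrees=True).as_matrix()
    normal = np.stack([-np.sin(heading), np.cos(heading)], axis=-1)
    pelvis_xy = path_pos + normal * (params.pelvis_lateral_amp_m * np.sin(phi))[:, None]
    pelvis_z = hip_height + params.pelvis_vertical_amp_m * np.sin(2.0 * phi + 1.2)
    pelvis_pos = np.concatenate([pelvis_xy, pelvis_z[:, None]], axis=1)

    half_w = anthro.pelvis_width / 2.0
    hip_L = pelvis_pos + np.einsum("tij,j->ti", R_pelvis,
                                   np.array([0.0, half_w, 0.0]))
    hip_R = pelvis_pos + np.einsum("tij,j->ti", R_pelvis,
                                   np.array([0.0, -half_w, 0.0]))

    ang_L = joint_angle_series(params, phi)
    ang_R = joint_angle_series(params, phi + right_phase, amp_scale=right_scale)

    RT_L, knee_L, RS_L, ankle_L = _leg_chain(R_pelvis, hip_L, ang_L, anthro)
    RT_R, knee_R, RS_R, ankle_R = _leg_chain(R_pelvis, hip_R, ang_R, anthro)

    # feet: heading yaw plus the foot-pitch wave; origin at the ankle
    RF_L = Rotation.from_euler(
        "ZY", np.stack([np.degrees(heading), -ang_L["foot"]], axis=1),
        degrees=True).as_matrix()
    RF_R = Rotation.from_euler(
        "ZY", np.stack([np.degrees(heading), -ang_R["foot"]], axis=1),
        degrees=True).as_matrix()

    rotations = {
        SegmentClass.Pelvis: R_pelvis,
        SegmentClass.LeftUpperLeg: RT_L, SegmentClass.RightUpperLeg: RT_R,
        SegmentClass.LeftLowerLeg: RS_L, SegmentClass.RightLowerLeg: RS_R,
        SegmentClass.LeftFoot: RF_L, SegmentClass.RightFoot: RF_R,
    }
    positions = {
        SegmentClass.Pelvis: pelvis_pos,
        SegmentClass.LeftUpperLeg: hip_L, SegmentClass.RightUpperLeg: hip_R,
        SegmentClass.LeftLowerLeg: knee_L, SegmentClass.RightLowerLeg: knee_R,
        SegmentClass.LeftFoot: ankle_L, SegmentClass.RightFoot: ankle_R,
    }
    return SkeletonPose(rotations, positions, SAMPLE_RATE_HZ)


def kinematic_chain_gaps(pose: SkeletonPose,
                         anthro: SubjectAnthropometrics) -> dict:
    """Per-joint distance between child origin and parent distal endpoint.

    For a correctly assembled chain every gap is numerically zero at every
    frame.  Returns ``joint name -> (T,) array of gap norms``.
    """
    gaps = {}
    for side in ("Left", "Right"):
        thigh = SegmentClass[f"{side}UpperLeg"]
        shank = SegmentClass[f"{side}LowerLeg"]
        foot = SegmentClass[f"{side}Foot"]
        sign = 1.0 if side == "Left" else -1.0
        hip_from_pelvis = (
            pose.positions[SegmentClass.Pelvis]
            + np.einsum("tij,j->ti", pose.rotations[SegmentClass.Pelvis],
                        np.array([0.0, sign * anthro.pelvis_width / 2.0, 0.0])))
        knee_from_thigh = (
            pose.positions[thigh]
            + np.einsum("tij,j->ti", pose.rotations[thigh],
                        np.array([0.0, 0.0, -anthro.thigh])))
        ankle_from_shank = (
            pose.positions[shank]
            + np.einsum("tij,j->ti", pose.rotations[shank],
                        np.array([0.0, 0.0, -anthro.shank])))
        gaps[f"{side}Hip"] = np.linalg.norm(
            hip_from_pelvis - pose.positions[thigh], axis=1)
        gaps[f"{side}Knee"] = np.linalg.norm(
            knee_from_thigh - pose.positions[shank], axis=1)
        gaps[f"{side}Ankle"] = np.linalg.norm(
            ankle_from_shank - pose.positions[foot], axis=1)
    return gaps


def default_i2s_positions(anthro: SubjectAnthropometrics) -> dict:
    """Constant sensor positions at the midpoint of each segment (meters)."""
    mid = {
        SegmentClass.Pelvis: np.zeros(3),
        SegmentClass.LeftUpperLeg: np.array([0.0, 0.0, -anthro.thigh / 2]),
        SegmentClass.RightUpperLeg: np.array([0.0, 0.0, -anthro.thigh / 2]),
        SegmentClass.LeftLowerLeg: np.array([0.0, 0.0, -anthro.shank / 2]),
        SegmentClass.RightLowerLeg: np.array([0.0, 0.0, -anthro.shank / 2]),
        SegmentClass.LeftFoot: np.array([anthro.foot / 2, 0.0, 0.0]),
        SegmentClass.RightFoot: np.array([anthro.foot / 2, 0.0, 0.0]),
    }
    return mid
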