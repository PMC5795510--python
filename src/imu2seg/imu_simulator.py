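"""Simulation of 6-channel IMU signals from rigid-body pose trajectories.

Given a time sequence of global segment poses and a constant sensor-to-
segment pose, the IMU pose trajectory follows from the frame transforms in
:mod:`imu2seg.body_model`.  From it, ideal gyroscope and accelerometer
signals are obtained by numerical differentiation:

* angular velocity from central differences of the orientation via the
  rotation logarithm, ``w_I(t) = log(R_GI(t-1)^T R_GI(t+1)) / (2 dt)``
  (one-sided at the ends) — an O(dt^2) scheme expressed in the sensor frame;
* specific force from second central differences of the position,
  ``f_I(t) = R_GI(t)^T (a_G(t) - g_G)`` with ``g_G = (0, 0, -9.81)`` m/s^2
  in the z-up global frame.  At rest the accelerometer therefore reads the
  gravity reaction (+9.81 m/s^2 along whatever sensor axis points up).

Measurement artifacts are then mimicked in three configurable stages:
zero-lag Butterworth pre-filtering of the input poses (order 8, 10 Hz cutoff
by default, to suppress motion-capture measurement noise), quantization to
the range/resolution of the emulated hardware, and zero-mean Gaussian noise
on the accelerometer channels (sigma = 1 m/s^2 by default; gyroscope noise
is considered negligible at this scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation

from imu2seg.body_model import I2SPose, SegmentClass, SkeletonPose, imu_pose_from_global
from imu2seg.rotmath import rotation_log

__all__ = [
    "ImuTrajectory",
    "ImuSignal",
    "QuantSpec",
    "NoiseSpec",
    "GRAVITY",
    "butter_zero_lag",
    "preprocess_pose",
    "angular_velocity",
    "specific_force",
    "ideal_signal",
    "quantize",
    "add_accel_noise",
    "simulate",
]

#: Gravity vector in the z-up global frame, m/s^2.
GRAVITY = np.array([0.0, 0.0, -9.81])


@dataclass
class ImuTrajectory:
    """Global IMU pose over time: R_GI (T,3,3), I_G (T,3) in meters."""

    R_GI: np.ndarray
    I_G: np.ndarray
    rate_hz: float = 60.0

    def __post_init__(self) -> None:
        self.R_GI = np.asarray(self.R_GI, float)
        self.I_G = np.asarray(self.I_G, float)
        if self.R_GI.ndim != 3 or self.R_GI.shape[1:] != (3, 3):
            raise ValueError("R_GI must have shape (T, 3, 3)")
        if self.I_G.shape != (self.R_GI.shape[0], 3):
            raise ValueError("I_G must have shape (T, 3)")
        if len(self.R_GI) < 3:
            raise ValueError("need at least 3 frames to differentiate")
        if self.rate_hz <= 0:
            raise ValueError("sample rate must be positive")

    def __len__(self) -> int:
        return len(self.R_GI)


@dataclass
class ImuSignal:
    """Accelerometer (m/s^2) and gyroscope (rad/s) series in the sensor frame."""

    acc: np.ndarray
    gyr: np.ndarray
    rate_hz: float = 60.0

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, float)
        self.gyr = np.asarray(self.gyr, float)
        if self.acc.shape != self.gyr.shape or self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise ValueError("acc and gyr must both have shape (T, 3)")
        if not (np.all(np.isfinite(self.acc)) and np.all(np.isfinite(self.gyr))):
            raise ValueError("IMU signal contains non-finite values")

    def __len__(self) -> int:
        return len(self.acc)

    def to_array(self) -> np.ndarray:
        """Stacked (T, 6) array, accelerometer channels first."""
        return np.concatenate([self.acc, self.gyr], axis=1)

    def to_csv(self, path) -> None:
        t = np.arange(len(self)) / self.rate_hz
        pd.DataFrame({
            "t": t,
            "ax": self.acc[:, 0], "ay": self.acc[:, 1], "az": self.acc[:, 2],
            "gx": self.gyr[:, 0], "gy": self.gyr[:, 1], "gz": self.gyr[:, 2],
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ImuSignal":
        df = pd.read_csv(path)
        rate = 1.0 / np.median(np.diff(df["t"])) if len(df) > 1 else 60.0
        return cls(acc=df[["ax", "ay", "az"]].to_numpy(float),
                   gyr=df[["gx", "gy", "gz"]].to_numpy(float),
                   rate_hz=float(round(rate, 6)))


@dataclass
class QuantSpec:
    """Symmetric full-scale range and bit depth per modality.

    Defaults emulate the wearable IMU class used for gait analysis:
    accelerometer +-160 m/s^2, gyroscope +-2000 deg/s, 16-bit converters.
    """

    acc_range: float = 160.0
    gyr_range: float = np.radians(2000.0)
    acc_bits: int = 16
    gyr_bits: int = 16

    def __post_init__(self) -> None:
        if self.acc_range <= 0 or self.gyr_range <= 0:
            raise ValueError("ranges must be positive")
        for b in (self.acc_bits, self.gyr_bits):
            if not 8 <= b <= 32:
                raise ValueError("bit depth must be in [8, 32]")


@dataclass
class NoiseSpec:
    """Accelerometer noise scale (standard deviation, m/s^2) and RNG seed."""

    sigma_a: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_a < 0:
            raise ValueError("noise scale must be non-negative")


# ----------------------------------------------------------------------
# filtering
# ----------------------------------------------------------------------

def butter_zero_lag(series: np.ndarray, order: int = 8, cutoff_hz: float = 10.0,
                    rate_hz: float = 60.0, *, effective_order: bool = True) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter along axis 0.

    The filter runs forward and backward (``filtfilt``), which squares the
    magnitude response; with ``effective_order=True`` (default) an order-
    ``order/2`` filter is designed per pass so the combined attenuation
    matches a single order-``order`` filter.
    """
    series = np.asarray(series, float)
    if cutoff_hz >= rate_hz / 2.0:
        raise ValueError("cutoff must be below the Nyquist frequency")
    design_order = max(1, order // 2) if effective_order else order
    if len(series) <= 3 * design_order:
        raise ValueError("series too short for the requested filter order")
    b, a = butter(design_order, cutoff_hz, fs=rate_hz)
    return filtfilt(b, a, series, axis=0)


def _filter_quaternions(q: np.ndarray, order: int, cutoff_hz: float,
                        rate_hz: float) -> np.ndarray:
    """Low-pass quaternion components with sign continuity, renormalized."""
    q = np.array(q, float)
    # enforce hemisphere continuity before treating components as signals
    for t in range(1, len(q)):
        if q[t] @ q[t - 1] < 0:
            q[t] = -q[t]
    qf = butter_zero_lag(q, order, cutoff_hz, rate_hz)
    return qf / np.linalg.norm(qf, axis=1, keepdims=True)


def preprocess_pose(pose: SkeletonPose, order: int = 8,
                    cutoff_hz: float = 10.0) -> SkeletonPose:
    """Zero-lag Butterworth smoothing of both orientations and positions."""
    rotations, positions = {}, {}
    for seg in SegmentClass:
        q = Rotation.from_matrix(pose.rotations[seg]).as_quat()[:, [3, 0, 1, 2]]
        qf = _filter_quaternions(q, order, cutoff_hz, pose.rate_hz)
        rotations[seg] = Rotation.from_quat(qf[:, [1, 2, 3, 0]]).as_matrix()
        positions[seg] = butter_zero_lag(pose.positions[seg], order,
                                         cutoff_hz, pose.rate_hz)
    return SkeletonPose(rotations, positions, pose.rate_hz)


# ----------------------------------------------------------------------
# differentiation
# ----------------------------------------------------------------------

def angular_velocity(traj: ImuTrajectory) -> np.ndarray:
    """Sensor-frame angular velocity (T, 3) in rad/s by central differences."""
    R = traj.R_GI
    dt = 1.0 / traj.rate_hz
    step = np.einsum("tij,tik->tjk", R[:-1], R[1:])  # R(t)^T R(t+1)
    step_angle = np.linalg.norm(rotation_log(step), axis=1)
    # near-half-turn steps are ambiguous in sign (aliasing); a small guard
    # band below 180 deg costs nothing physically (>10^4 deg/s at 60 Hz)
    if np.any(step_angle >= np.pi - 1e-3):
        raise ValueError("frame-to-frame rotation approaches 180 deg: "
                         "aliased or undersampled input")
    omega = np.empty((len(R), 3))
    if len(R) > 2:
        central = np.einsum("tij,tik->tjk", R[:-2], R[2:])
        omega[1:-1] = rotation_log(central) / (2.0 * dt)
    omega[0] = rotation_log(step[0]) / dt
    omega[-1] = rotation_log(step[-1]) / dt
    return omega


def specific_force(traj: ImuTrajectory, gravity: np.ndarray = GRAVITY) -> np.ndarray:
    """Sensor-frame specific force (T, 3) in m/s^2.

    Linear acceleration from second central differences of the position,
    minus gravity, rotated into the sensor frame.  End frames reuse the
    nearest interior acceleration estimate.
    """
    p = traj.I_G
    dt = 1.0 / traj.rate_hz
    a_G = np.empty_like(p)
    a_G[1:-1] = (p[2:] - 2.0 * p[1:-1] + p[:-2]) / dt**2
    a_G[0] = a_G[1]
    a_G[-1] = a_G[-2]
    g = np.asarray(gravity, float).reshape(3)
    return np.einsum("tij,ti->tj", traj.R_GI, a_G - g)


def ideal_signal(traj: ImuTrajectory) -> ImuSignal:
    """Noise-free, unquantized IMU signal for a pose trajectory."""
    return ImuSignal(acc=specific_force(traj), gyr=angular_velocity(traj),
                     rate_hz=traj.rate_hz)


# ----------------------------------------------------------------------
# measurement artifacts
# ----------------------------------------------------------------------

def _quantize_channel(x: np.ndarray, full_range: float, bits: int) -> np.ndarray:
    step = 2.0 * full_range / (2**bits - 1)
    q = np.round(np.clip(x, -full_range, full_range) / step) * step
    return np.clip(q, -full_range, full_range)


def quantize(signal: ImuSignal, spec: QuantSpec = QuantSpec()) -> ImuSignal:
    """Clip to the sensor range and round to its digital resolution."""
    return ImuSignal(
        acc=_quantize_channel(signal.acc, spec.acc_range, spec.acc_bits),
        gyr=_quantize_channel(signal.gyr, spec.gyr_range, spec.gyr_bits),
        rate_hz=signal.rate_hz,
    )


def add_accel_noise(signal: ImuSignal, spec: NoiseSpec = NoiseSpec(),
                    rng: np.random.Generator | None = None) -> ImuSignal:
    """Add i.i.d. zero-mean Gaussian noise to the accelerometer channels."""
    if spec.sigma_a == 0.0:
        return ImuSignal(signal.acc.copy(), signal.gyr.copy(), signal.rate_hz)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.sigma_a, size=signal.acc.shape)
    return ImuSignal(signal.acc + noise, signal.gyr.copy(), signal.rate_hz)


# ----------------------------------------------------------------------
# end-to-end simulation
# ----------------------------------------------------------------------

def simulate(pose: SkeletonPose, i2s: dict, quant: QuantSpec | None = None,
             noise: NoiseSpec | None = None, *, preprocess: bool = False,
             rng: np.random.Generator | None = None) -> dict:
    """Simulate one IMU signal per segment from skeleton kinematics.

    Parameters
    ----------
    pose : global segment poses (optionally already smoothed).
    i2s : mapping ``SegmentClass -> I2SPose`` (constant over the take).
    quant, noise : measurement-artifact stages; ``None`` skips a stage.
    preprocess : apply the zero-lag Butterworth filter to the poses first
        (use for raw motion-capture input; synthetic kinematics are smooth).
    rng : optional shared generator; defaults to one seeded from ``noise.seed``
        and consumed in segment-enum order, so results are reproducible.
    """
    if preprocess:
        pose = preprocess_pose(pose)
    if noise is not None and rng is None:
        rng = np.random.default_rng(noise.seed)
    out = {}
    for seg in sorted(i2s, key=int):
        R_GI, I_G = imu_pose_from_global(pose.rotations[seg],
                                         pose.positions[seg], i2s[seg])
        sig = ideal_signal(ImuTrajectory(R_GI, I_G, pose.rate_hz))
        if quant is not None:
            sig = quantize(sig, quant)
        if noise is not None:
            sig = add_accel_noise(sig, noise, rng=rng)
        out[seg] = sig
    return out
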