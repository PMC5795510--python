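"""Lower-body skeleton, frame transforms, and alignment-variation sampling.

Three coordinate frames appear throughout:

* ``G`` — fixed global frame, z-up;
* ``S`` — anatomical frame of a body segment (legs: z longitudinal pointing
  proximally, x anterior, y by right-hand rule; feet: x anterior along the
  foot, z up);
* ``I`` — frame of the IMU mounted on the segment.

``R_GS, S_G`` and ``R_GI, I_G`` denote segment and IMU poses with respect to
the global frame.  The sensor-to-segment ("I2S") pose is::

    R_SI = (R_GS)^T R_GI          I_S = (R_GS)^T (I_G - S_G)

and, inversely, IMU poses follow from segment poses and a constant I2S pose::

    R_GI = R_GS R_SI              I_G = R_GS I_S + S_G

The I2S position is assumed constant at the midpoint of the segment.

Alignment variations
--------------------
Training data for the alignment regressor is augmented by systematically
rotating the base mounting orientation about two axes — the IMU's own z-axis
(the outward surface normal of a capsule-shaped segment) and a
segment-specific longitudinal axis ``a``::

    R_hat = R_a(theta2) . R_SI . R_z(theta1)

with both angles drawn from an equidistant grid of the full circle (default
45-degree steps, giving 8 x 8 = 64 variations).  ``a`` is the segment z-axis
for the four leg segments, the y-axis for the pelvis, and the forward-and-
down vector (0.9, 0, -0.4) (normalized) for the feet, which approximates the
segment-frame direction from the foot origin to the head of the second
metatarsal projected onto the ground.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import h5py
import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from imu2seg import rotmath
from imu2seg.rotmath import UnitQuaternion, require_rotation, rot_axis, rot_z

__all__ = [
    "SegmentClass",
    "SkeletonPose",
    "I2SPose",
    "VariationSpec",
    "i2s_from_global",
    "imu_pose_from_global",
    "variation_axis_for",
    "sample_alignment_variations",
    "default_variation_angles",
    "default_base_alignments",
    "LEFT_RIGHT_PAIRS",
    "MERGED_CLASS_NAMES",
]


class SegmentClass(IntEnum):
    """The seven lower-body segments an IMU can be assigned to."""

    LeftFoot = 0
    LeftLowerLeg = 1
    LeftUpperLeg = 2
    Pelvis = 3
    RightUpperLeg = 4
    RightLowerLeg = 5
    RightFoot = 6


#: Mirror pairs merged when scoring assignment without left/right switches.
LEFT_RIGHT_PAIRS = (
    (SegmentClass.LeftFoot, SegmentClass.RightFoot),
    (SegmentClass.LeftLowerLeg, SegmentClass.RightLowerLeg),
    (SegmentClass.LeftUpperLeg, SegmentClass.RightUpperLeg),
)

MERGED_CLASS_NAMES = ("Foot", "LowerLeg", "UpperLeg", "Pelvis")


@dataclass
class SkeletonPose:
    """Global poses of all seven segments over time.

    rotations : dict segment -> (T, 3, 3) array of R_GS
    positions : dict segment -> (T, 3) array of S_G in meters
    rate_hz   : sampling rate
    """

    rotations: dict
    positions: dict
    rate_hz: float = 60.0

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError("sample rate must be positive")
        missing = [s for s in SegmentClass if s not in self.rotations]
        if missing:
            raise ValueError(f"missing segments: {missing}")
        lengths = {len(self.rotations[s]) for s in SegmentClass}
        lengths |= {len(self.positions[s]) for s in SegmentClass}
        if len(lengths) != 1:
            raise ValueError("all segments must have equal frame counts")

    @property
    def n_frames(self) -> int:
        return len(self.rotations[SegmentClass.Pelvis])

    # ------------------------------------------------------------------
    # serialization: tidy CSV and HDF5
    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for seg in SegmentClass:
            xyzw = Rotation.from_matrix(self.rotations[seg]).as_quat()
            q = rotmath.canonicalize_quat_array(xyzw[:, [3, 0, 1, 2]])
            p = self.positions[seg]
            df = pd.DataFrame({
                "frame": np.arange(self.n_frames),
                "segment": seg.name,
                "qw": q[:, 0], "qx": q[:, 1], "qy": q[:, 2], "qz": q[:, 3],
                "px": p[:, 0], "py": p[:, 1], "pz": p[:, 2],
            })
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, rate_hz: float = 60.0) -> "SkeletonPose":
        rotations, positions = {}, {}
        for seg in SegmentClass:
            sub = df[df["segment"] == seg.name].sort_values("frame")
            if sub.empty:
                raise ValueError(f"segment {seg.name} missing from table")
            q = sub[["qw", "qx", "qy", "qz"]].to_numpy(dtype=float)
            q /= np.linalg.norm(q, axis=1, keepdims=True)
            rotations[seg] = Rotation.from_quat(q[:, [1, 2, 3, 0]]).as_matrix()
            positions[seg] = sub[["px", "py", "pz"]].to_numpy(dtype=float)
        return cls(rotations, positions, rate_hz)

    @classmethod
    def from_csv(cls, path, rate_hz: float = 60.0) -> "SkeletonPose":
        return cls.from_frame(pd.read_csv(path), rate_hz)

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["rate_hz"] = self.rate_hz
            for seg in SegmentClass:
                g = f.create_group(seg.name)
                g.create_dataset("R_GS", data=self.rotations[seg])
                g.create_dataset("S_G", data=self.positions[seg])

    @classmethod
    def from_hdf5(cls, path) -> "SkeletonPose":
        with h5py.File(path, "r") as f:
            rate = float(f.attrs["rate_hz"])
            rotations = {s: f[s.name]["R_GS"][()] for s in SegmentClass}
            positions = {s: f[s.name]["S_G"][()] for s in SegmentClass}
        return cls(rotations, positions, rate)


@dataclass
class I2SPose:
    """Constant sensor-to-segment pose: orientation R_SI and position I_S (m)."""

    R_SI: np.ndarray
    I_S: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.R_SI = require_rotation(self.R_SI, tol=1e-8)
        self.I_S = np.asarray(self.I_S, dtype=float).reshape(3)

    @property
    def quaternion(self) -> UnitQuaternion:
        return UnitQuaternion.from_matrix(self.R_SI)


# ----------------------------------------------------------------------
# frame transforms
# ----------------------------------------------------------------------

def i2s_from_global(R_GS, S_G, R_GI, I_G) -> I2SPose:
    """Sensor-to-segment pose from global segment and IMU poses."""
    R_GS = np.asarray(R_GS, float)
    return I2SPose(R_SI=R_GS.T @ np.asarray(R_GI, float),
                   I_S=R_GS.T @ (np.asarray(I_G, float) - np.asarray(S_G, float)))


def imu_pose_from_global(R_GS, S_G, i2s: I2SPose):
    """Global IMU pose from the segment pose and a constant I2S pose.

    Vectorized over leading frame axes: ``R_GS`` may be (..., 3, 3) and
    ``S_G`` (..., 3).
    """
    R_GS = np.asarray(R_GS, float)
    S_G = np.asarray(S_G, float)
    R_GI = R_GS @ i2s.R_SI
    I_G = np.einsum("...ij,j->...i", R_GS, i2s.I_S) + S_G
    return R_GI, I_G


# ----------------------------------------------------------------------
# alignment-variation sampling
# ----------------------------------------------------------------------

_FOOT_AXIS = np.array([0.9, 0.0, -0.4])


def variation_axis_for(segment: SegmentClass) -> np.ndarray:
    """Segment-frame axis about which mounting variations are rotated."""
    if segment == SegmentClass.Pelvis:
        return np.array([0.0, 1.0, 0.0])
    if segment in (SegmentClass.LeftFoot, SegmentClass.RightFoot):
        return _FOOT_AXIS / np.linalg.norm(_FOOT_AXIS)
    return np.array([0.0, 0.0, 1.0])


def default_variation_angles(step_deg: float = 45.0) -> np.ndarray:
    """Equidistant full-circle angle grid, default {0, 45, ..., 315} degrees."""
    n = int(round(360.0 / step_deg))
    return np.arange(n) * (360.0 / n)


@dataclass
class VariationSpec:
    """Specification of the systematic alignment-variation grid.

    angles_deg : the angle set (both rotations draw from the same grid)
    segment_axis : unit axis ``a`` in the segment frame
    imu_axis : unit axis in the IMU frame (the sensor's z-axis by default)
    base_alignment : the assumed initial mounting orientation R_SI
    """

    angles_deg: np.ndarray
    segment_axis: np.ndarray
    base_alignment: np.ndarray
    imu_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, float).reshape(-1)
        if self.angles_deg.size == 0:
            raise ValueError("angle set must be non-empty")
        if np.any((self.angles_deg < 0) | (self.angles_deg >= 360)):
            raise ValueError("angles must lie in [0, 360)")
        self.segment_axis = np.asarray(self.segment_axis, float).reshape(3)
        self.segment_axis = self.segment_axis / np.linalg.norm(self.segment_axis)
        self.imu_axis = np.asarray(self.imu_axis, float).reshape(3)
        self.imu_axis = self.imu_axis / np.linalg.norm(self.imu_axis)
        self.base_alignment = require_rotation(self.base_alignment, tol=1e-8)

    @classmethod
    def for_segment(cls, segment: SegmentClass, base_alignment=None,
                    step_deg: float = 45.0) -> "VariationSpec":
        if base_alignment is None:
            base_alignment = default_base_alignments()[segment]
        return cls(angles_deg=default_variation_angles(step_deg),
                   segment_axis=variation_axis_for(segment),
                   base_alignment=base_alignment)


def sample_alignment_variations(spec: VariationSpec) -> list:
    """Enumerate all ``|angles|^2`` varied alignments, theta1-major.

    Element ``l = i * |angles| + j`` is
    ``R_a(theta2=angles[j]) . R_SI . R_imu_axis(theta1=angles[i])``.
    """
    out = []
    for th1 in spec.angles_deg:
        Rz = rot_axis(spec.imu_axis, th1)
        for th2 in spec.angles_deg:
            Ra = rot_axis(spec.segment_axis, th2)
            out.append(Ra @ spec.base_alignment @ Rz)
    return out


# ----------------------------------------------------------------------
# default base mounting orientations
# ----------------------------------------------------------------------

def default_base_alignments() -> dict:
    """A plausible default mounting (IMU z outward from the segment surface).

    Legs: IMU strapped on the anterior surface, sensor z pointing anteriorly
    (segment +x), sensor x pointing down the bone (segment -z).  Pelvis: IMU
    on the sacrum, z posterior.  Feet: IMU on the instep, z up, x forward.
    Columns of R_SI are the IMU axes expressed in the segment frame.
    """
    leg = np.column_stack([[0.0, 0.0, -1.0],   # I_x -> -z_S (down the bone)
                           [0.0, 1.0, 0.0],    # I_y -> +y_S
                           [1.0, 0.0, 0.0]])   # I_z -> +x_S (anterior normal)
    pelvis = np.column_stack([[0.0, 0.0, 1.0],    # I_x -> +z_S (up)
                              [0.0, 1.0, 0.0],    # I_y -> +y_S
                              [-1.0, 0.0, 0.0]])  # I_z -> -x_S (posterior)
    foot = rot_z(0.0)  # identity: x forward along the foot, z up (instep)
    out = {}
    for seg in SegmentClass:
        if seg == SegmentClass.Pelvis:
            out[seg] = pelvis.copy()
        elif seg in (SegmentClass.LeftFoot, SegmentClass.RightFoot):
            out[seg] = foot.copy()
        else:
            out[seg] = leg.copy()
        require_rotation(out[seg])
    return out
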