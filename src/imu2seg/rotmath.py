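"""Rotation algebra: quaternions, matrices, stereographic projection, Euler-XYZ.

Conventions
-----------
* Quaternions are Hamilton, scalar-first ``(w, x, y, z)``, unit norm, and
  canonicalized to ``w >= 0``.  The canonical form removes the double cover
  of SO(3) so that the regression target of the alignment network is unique.
* Angles cross the public API in **degrees** (matching how alignment errors
  are reported in gait analysis); internal math is in radians.
* The stereographic projection maps a canonical unit quaternion to the
  3-vector ``s = (x, y, z) / (1 + w)`` — projection from the pole
  ``(-1, 0, 0, 0)``, so the identity rotation maps to the origin and the
  map has no singularity near the identity.  Its inverse is rational:
  ``w = (1 - |s|^2) / (1 + |s|^2)``, ``(x, y, z) = 2 s / (1 + |s|^2)``.
* Euler decomposition is **intrinsic** X-then-Y-then-Z, reported in degrees
  with ``|a_x|, |a_z| <= 180`` and ``|a_y| <= 90``.

Matrix conversions, Euler factorization and the rotation logarithm are
delegated to :class:`scipy.spatial.transform.Rotation`; this module adds the
quaternion canonicalization, the stereographic parametrization, and small
validated wrappers used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "UnitQuaternion",
    "require_rotation",
    "rot_axis",
    "rot_x",
    "rot_y",
    "rot_z",
    "quat_from_axis_angle",
    "stereographic_project",
    "stereographic_unproject",
    "stereo_to_quat_array",
    "quat_array_to_stereo",
    "canonicalize_quat_array",
    "euler_xyz_decompose",
    "euler_xyz_compose",
    "rotation_log",
    "rotation_exp",
]

_UNIT_TOL = 1e-9


def _as_unit_vec3(v, name: str = "axis") -> np.ndarray:
    v = np.asarray(v, dtype=float).reshape(3)
    n = np.linalg.norm(v)
    if n <= 0.0 or not np.isfinite(n):
        raise ValueError(f"{name} must be a nonzero finite 3-vector")
    return v / n


@dataclass(frozen=True)
class UnitQuaternion:
    """Unit quaternion ``w + xi + yj + zk`` (Hamilton), canonical ``w >= 0``."""

    w: float
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        n = np.sqrt(self.w**2 + self.x**2 + self.y**2 + self.z**2)
        if abs(n - 1.0) > 1e-6:
            raise ValueError(f"quaternion norm {n:.9f} is not 1")
        # renormalize and canonicalize (w >= 0) in-place on the frozen fields
        sgn = -1.0 if self.w < 0.0 else 1.0
        object.__setattr__(self, "w", sgn * self.w / n)
        object.__setattr__(self, "x", sgn * self.x / n)
        object.__setattr__(self, "y", sgn * self.y / n)
        object.__setattr__(self, "z", sgn * self.z / n)

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls) -> "UnitQuaternion":
        return cls(1.0, 0.0, 0.0, 0.0)

    @classmethod
    def from_wxyz(cls, q) -> "UnitQuaternion":
        w, x, y, z = np.asarray(q, dtype=float).reshape(4)
        return cls(w, x, y, z)

    @classmethod
    def from_matrix(cls, R) -> "UnitQuaternion":
        x, y, z, w = Rotation.from_matrix(np.asarray(R, dtype=float)).as_quat()
        return cls(w, x, y, z)

    @classmethod
    def from_axis_angle(cls, axis, angle_deg: float) -> "UnitQuaternion":
        return quat_from_axis_angle(axis, angle_deg)

    # -- views --------------------------------------------------------
    @property
    def wxyz(self) -> np.ndarray:
        return np.array([self.w, self.x, self.y, self.z])

    @property
    def vec(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    def to_matrix(self) -> np.ndarray:
        return Rotation.from_quat([self.x, self.y, self.z, self.w]).as_matrix()

    # -- algebra ------------------------------------------------------
    def conjugate(self) -> "UnitQuaternion":
        return UnitQuaternion(self.w, -self.x, -self.y, -self.z)

    inverse = conjugate

    def __mul__(self, other: "UnitQuaternion") -> "UnitQuaternion":
        w1, v1 = self.w, self.vec
        w2, v2 = other.w, other.vec
        w = w1 * w2 - v1 @ v2
        v = w1 * v2 + w2 * v1 + np.cross(v1, v2)
        return UnitQuaternion(w, *v)

    def rotate(self, v) -> np.ndarray:
        """Rotate a 3-vector by this quaternion (same rotation as to_matrix())."""
        return self.to_matrix() @ np.asarray(v, dtype=float).reshape(3)

    def angle_to(self, other: "UnitQuaternion") -> float:
        """Geodesic angle between the two rotations, degrees in [0, 180]."""
        d = self.conjugate() * other
        return float(np.degrees(2.0 * np.arccos(np.clip(abs(d.w), -1.0, 1.0))))


# ---------------------------------------------------------------------
# rotation matrices
# ---------------------------------------------------------------------

def require_rotation(R, tol: float = _UNIT_TOL) -> np.ndarray:
    """Validate that ``R`` is a proper rotation (orthonormal, det +1)."""
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"expected 3x3 matrix, got {R.shape}")
    if not np.allclose(R.T @ R, np.eye(3), atol=max(tol, 1e-9)):
        raise ValueError("matrix is not orthonormal")
    if abs(np.linalg.det(R) - 1.0) > max(tol, 1e-9):
        raise ValueError("matrix determinant is not +1")
    return R


def rot_axis(axis, angle_deg: float) -> np.ndarray:
    """Rotation matrix of ``angle_deg`` about ``axis`` (normalized internally)."""
    if float(angle_deg) == 0.0:
        return np.eye(3)
    a = _as_unit_vec3(axis)
    return Rotation.from_rotvec(np.radians(angle_deg) * a).as_matrix()


def rot_x(angle_deg: float) -> np.ndarray:
    return Rotation.from_euler("x", angle_deg, degrees=True).as_matrix()


def rot_y(angle_deg: float) -> np.ndarray:
    return Rotation.from_euler("y", angle_deg, degrees=True).as_matrix()


def rot_z(angle_deg: float) -> np.ndarray:
    return Rotation.from_euler("z", angle_deg, degrees=True).as_matrix()


def quat_from_axis_angle(axis, angle_deg: float) -> UnitQuaternion:
    """Unit quaternion of a rotation by ``angle_deg`` about ``axis``.

    A zero axis is a domain error unless the angle is 0 (identity).
    """
    if float(angle_deg) == 0.0:
        return UnitQuaternion.identity()
    a = _as_unit_vec3(axis)
    half = 0.5 * np.radians(angle_deg)
    return UnitQuaternion(np.cos(half), *(np.sin(half) * a))


# ---------------------------------------------------------------------
# stereographic parametrization
# ---------------------------------------------------------------------

def stereographic_project(q: UnitQuaternion) -> np.ndarray:
    """Map a canonical unit quaternion to its stereographic 3-vector.

    ``s = (x, y, z) / (1 + w)``.  Canonical quaternions have ``w >= 0`` so
    the denominator is at least 1 and ``|s| <= 1``.
    """
    if q.w <= -1.0 + 1e-12:
        raise ValueError("stereographic projection undefined at w = -1")
    return q.vec / (1.0 + q.w)


def stereographic_unproject(s) -> UnitQuaternion:
    """Inverse stereographic map; total on R^3, exact inverse for ``w >= 0``."""
    s = np.asarray(s, dtype=float).reshape(3)
    n2 = float(s @ s)
    w = (1.0 - n2) / (1.0 + n2)
    v = 2.0 * s / (1.0 + n2)
    return UnitQuaternion(w, *v)


def canonicalize_quat_array(q: np.ndarray) -> np.ndarray:
    """Flip signs so every row of an (N, 4) wxyz array has ``w >= 0``."""
    q = np.asarray(q, dtype=float)
    sgn = np.where(q[..., :1] < 0.0, -1.0, 1.0)
    return q * sgn


def quat_array_to_stereo(q: np.ndarray) -> np.ndarray:
    """Vectorized stereographic projection of an (N, 4) wxyz array."""
    q = canonicalize_quat_array(q)
    return q[..., 1:] / (1.0 + q[..., :1])


def stereo_to_quat_array(s: np.ndarray) -> np.ndarray:
    """Vectorized inverse stereographic map, (N, 3) -> (N, 4) wxyz."""
    s = np.asarray(s, dtype=float)
    n2 = np.sum(s * s, axis=-1, keepdims=True)
    w = (1.0 - n2) / (1.0 + n2)
    v = 2.0 * s / (1.0 + n2)
    return np.concatenate([w, v], axis=-1)


# ---------------------------------------------------------------------
# Euler XYZ and the rotation logarithm
# ---------------------------------------------------------------------

def euler_xyz_decompose(R) -> np.ndarray:
    """Intrinsic X-then-Y-then-Z Euler angles of ``R``, in degrees.

    At gimbal lock (|a_y| = 90 deg) the z-angle is set to 0 and the residual
    is folded into the x-angle.  Accepts a single 3x3 matrix or a stack
    (N, 3, 3); returns shape (3,) or (N, 3).
    """
    R = np.asarray(R, dtype=float)
    return Rotation.from_matrix(R).as_euler("XYZ", degrees=True)


def euler_xyz_compose(angles_deg) -> np.ndarray:
    """Recompose a rotation from intrinsic XYZ Euler angles in degrees."""
    return Rotation.from_euler("XYZ", np.asarray(angles_deg, dtype=float),
                               degrees=True).as_matrix()


def rotation_log(R) -> np.ndarray:
    """Axis-angle (rotation-vector) logarithm of ``R`` in radians, |log| <= pi.

    Accepts a single matrix or a stack (N, 3, 3).
    """
    R = np.asarray(R, dtype=float)
    return Rotation.from_matrix(R).as_rotvec()


def rotation_exp(v) -> np.ndarray:
    """Matrix exponential of a rotation vector (radians)."""
    return Rotation.from_rotvec(np.asarray(v, dtype=float)).as_matrix()
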