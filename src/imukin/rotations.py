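"""Rotation algebra on unit quaternions, rotation matrices and axis-angle form.

Conventions used throughout the package:

* Quaternions are scalar-first ``(w, x, y, z)`` numpy arrays of shape (4,).
  ``q`` and ``-q`` represent the same rotation; functions that return a
  quaternion canonicalize to ``w >= 0``.
* A quaternion/matrix maps *sensor-frame* (or segment-frame) vectors into the
  earth/ground frame: ``v_earth = R(q) @ v_local``.
* Angles are radians internally; file and CLI interfaces convert to degrees.

The scalar distance between two orientations is the angle of the axis-angle
form of their relative rotation,

    theta = arccos((tr(Ra^T Rb) - 1) / 2),

which equals ``2 * arccos(|<qa, qb>|)`` on the corresponding quaternions.
This single metric underpins sensor-fusion error, the inverse-kinematics
objective, and sensor screening.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

__all__ = [
    "InvalidRotationError",
    "AxisAngle",
    "quat_normalize",
    "quat_canonical",
    "quat_conjugate",
    "quat_multiply",
    "quat_rotate",
    "quat_from_axis_angle",
    "quat_to_axis_angle",
    "quat_to_rotvec",
    "quat_from_rotvec",
    "quat_to_matrix",
    "matrix_to_quat",
    "relative_rotation",
    "rotation_angle",
    "orientation_difference",
]

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])


class InvalidRotationError(ValueError):
    """Raised when an input does not represent a valid 3-D rotation."""


class AxisAngle(NamedTuple):
    """A rotation as a unit axis and an angle in ``[0, pi]`` radians.

    For the identity rotation (angle 0) the axis is undefined; by convention
    it is reported as ``(1, 0, 0)``.
    """

    axis: np.ndarray
    angle: float


def quat_normalize(q) -> np.ndarray:
    """Return ``q / |q|``; reject near-zero quaternions."""
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q)
    if n < 1e-12:
        raise InvalidRotationError("zero-norm quaternion cannot be normalized")
    return q / n


def quat_canonical(q) -> np.ndarray:
    """Flip sign so the scalar part is non-negative (double-cover convention)."""
    q = np.asarray(q, dtype=float)
    return -q if q[0] < 0.0 else q


def quat_conjugate(q) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return np.array([q[0], -q[1], -q[2], -q[3]])


def quat_multiply(a, b) -> np.ndarray:
    """Hamilton product ``a * b`` (apply ``b`` first, then ``a``)."""
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    return np.array(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ]
    )


def quat_rotate(q, v) -> np.ndarray:
    """Rotate vector ``v`` by quaternion ``q`` (same as ``R(q) @ v``)."""
    w = q[0]
    r = np.asarray(q[1:], dtype=float)
    v = np.asarray(v, dtype=float)
    # R(q) v = (w^2 - r.r) v + 2 r (r.v) + 2 w (r x v)
    return (w * w - r @ r) * v + 2.0 * r * (r @ v) + 2.0 * w * np.cross(r, v)


def quat_from_axis_angle(axis, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise InvalidRotationError("rotation axis must be non-zero")
    half = 0.5 * float(angle)
    q = np.empty(4)
    q[0] = np.cos(half)
    q[1:] = np.sin(half) * axis / n
    return quat_canonical(q)


def quat_to_axis_angle(q) -> AxisAngle:
    q = quat_canonical(quat_normalize(q))
    sin_half = np.linalg.norm(q[1:])
    angle = 2.0 * np.arctan2(sin_half, q[0])
    if sin_half < 1e-12:
        return AxisAngle(np.array([1.0, 0.0, 0.0]), 0.0)
    return AxisAngle(q[1:] / sin_half, float(angle))


def quat_to_rotvec(q) -> np.ndarray:
    """Logarithmic map: rotation vector ``axis * angle`` (radians).

    Stable near the identity (series expansion of angle/sin(angle/2)).
    """
    q = quat_canonical(quat_normalize(q))
    w = q[0]
    v = q[1:]
    sin_half = np.linalg.norm(v)
    if sin_half < 1e-8:
        # angle/sin(half) -> 2 + angle^2/12 ... ; first term suffices here
        return 2.0 * v
    angle = 2.0 * np.arctan2(sin_half, w)
    return v * (angle / sin_half)


def quat_from_rotvec(rv) -> np.ndarray:
    rv = np.asarray(rv, dtype=float)
    angle = np.linalg.norm(rv)
    if angle < 1e-12:
        q = np.array([1.0, 0.5 * rv[0], 0.5 * rv[1], 0.5 * rv[2]])
        return quat_normalize(q)
    return quat_from_axis_angle(rv / angle, angle)


def quat_to_matrix(q) -> np.ndarray:
    """Rotation matrix of a quaternion (renormalized internally)."""
    w, x, y, z = quat_normalize(q)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _check_matrix(R, tol: float = 1e-6) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise InvalidRotationError(f"rotation matrix must be 3x3, got {R.shape}")
    err = np.max(np.abs(R.T @ R - np.eye(3)))
    if err > tol:
        raise InvalidRotationError(
            f"matrix is not orthonormal (max |R^T R - I| = {err:.3g} > {tol:g})"
        )
    if np.linalg.det(R) < 0.0:
        raise InvalidRotationError("matrix has negative determinant (reflection)")
    return R


def matrix_to_quat(R) -> np.ndarray:
    """Quaternion of a rotation matrix, Shepperd branch selection, ``w >= 0``."""
    R = _check_matrix(R)
    tr = R[0, 0] + R[1, 1] + R[2, 2]
    # pick the largest of (w, x, y, z) as pivot for numerical stability
    choices = [tr, R[0, 0], R[1, 1], R[2, 2]]
    i = int(np.argmax(choices))
    q = np.empty(4)
    if i == 0:
        s = np.sqrt(tr + 1.0) * 2.0
        q[0] = 0.25 * s
        q[1] = (R[2, 1] - R[1, 2]) / s
        q[2] = (R[0, 2] - R[2, 0]) / s
        q[3] = (R[1, 0] - R[0, 1]) / s
    elif i == 1:
        s = np.sqrt(1.0 + R[0, 0] - R[1, 1] - R[2, 2]) * 2.0
        q[0] = (R[2, 1] - R[1, 2]) / s
        q[1] = 0.25 * s
        q[2] = (R[0, 1] + R[1, 0]) / s
        q[3] = (R[0, 2] + R[2, 0]) / s
    elif i == 2:
        s = np.sqrt(1.0 + R[1, 1] - R[0, 0] - R[2, 2]) * 2.0
        q[0] = (R[0, 2] - R[2, 0]) / s
        q[1] = (R[0, 1] + R[1, 0]) / s
        q[2] = 0.25 * s
        q[3] = (R[1, 2] + R[2, 1]) / s
    else:
        s = np.sqrt(1.0 + R[2, 2] - R[0, 0] - R[1, 1]) * 2.0
        q[0] = (R[1, 0] - R[0, 1]) / s
        q[1] = (R[0, 2] + R[2, 0]) / s
        q[2] = (R[1, 2] + R[2, 1]) / s
        q[3] = 0.25 * s
    return quat_canonical(quat_normalize(q))


def relative_rotation(Ra, Rb) -> np.ndarray:
    """Relative rotation ``Ra^T @ Rb`` between two ground-frame orientations."""
    Ra = np.asarray(Ra, dtype=float)
    Rb = np.asarray(Rb, dtype=float)
    return Ra.T @ Rb


def rotation_angle(R) -> float:
    """Angle of the axis-angle form of ``R``, in ``[0, pi]`` radians.

    The arccos argument is clamped to [-1, 1] so floating-point error can
    never produce NaN.
    """
    R = np.asarray(R, dtype=float)
    c = (R[0, 0] + R[1, 1] + R[2, 2] - 1.0) / 2.0
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def orientation_difference(qa, qb) -> float:
    """Angular distance (radians) between two orientations, sign-insensitive.

    Equals ``rotation_angle(relative_rotation(R(qa), R(qb)))``; computed on
    quaternions via the relative rotation ``qa* qb`` with an atan2 form,
    which keeps full precision near zero where arccos of the dot loses it.
    """
    qa = quat_normalize(qa)
    qb = quat_normalize(qb)
    rel = quat_multiply(quat_conjugate(qa), qb)
    sin_half = np.linalg.norm(rel[1:])
    return 2.0 * float(np.arctan2(sin_half, abs(rel[0])))
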