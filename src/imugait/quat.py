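"""Quaternion algebra and strapdown attitude primitives.

Quaternions are stored as length-4 ``numpy`` arrays ``[w, x, y, z]``
(scalar-first, Hamilton convention).  A quaternion encodes the rotation from
the sensor (body) frame to the global frame: ``v_global = R(q) @ v_sensor``.
``q`` and ``-q`` represent the same rotation; :func:`canonical` picks the
representative with ``w >= 0``.

Angles at the public interfaces are in degrees; everything internal is in
radians.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import DegenerateOrientationError, InvalidArgumentError

__all__ = [
    "quat_identity",
    "canonical",
    "normalize",
    "quat_multiply",
    "quat_conjugate",
    "quat_to_matrix",
    "quat_from_axis_angle",
    "rotate_vector",
    "rotate_vector_inverse",
    "integrate_quat",
    "euler_zyx",
    "quat_from_euler_zyx",
    "quat_angle_deg",
]

_GIMBAL_GUARD_DEG = 0.5


def quat_identity() -> np.ndarray:
    return np.array([1.0, 0.0, 0.0, 0.0])


def normalize(q: np.ndarray) -> np.ndarray:
    """Return the unit quaternion along ``q``."""
    q = np.asarray(q, dtype=float)
    n = math.sqrt(q[0] * q[0] + q[1] * q[1] + q[2] * q[2] + q[3] * q[3])
    if n == 0.0 or not math.isfinite(n):
        raise InvalidArgumentError("cannot normalize zero or non-finite quaternion")
    return q / n

def canonical(q: np.ndarray) -> np.ndarray:
    """Unit quaternion with non-negative scalar part (q and -q are one rotation)."""
    q = normalize(q)
    return -q if q[0] < 0.0 else q


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product ``a ⊗ b``.

    Composition matches rotation matrices: ``R(a ⊗ b) = R(a) @ R(b)``, i.e.
    ``a ⊗ b`` rotates first by ``b`` then by ``a`` when acting on column
    vectors.
    """
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    out = np.array(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ]
    )
    if not np.all(np.isfinite(out)):
        raise InvalidArgumentError("non-finite quaternion product")
    return out


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    return np.array([q[0], -q[1], -q[2], -q[3]])


def quat_to_matrix(q: np.ndarray, *, tol: float = 1e-6) -> np.ndarray:
    """Rotation matrix ``R(q)`` mapping sensor-frame vectors to the global frame."""
    q = np.asarray(q, dtype=float)
    n2 = float(q @ q)
    if abs(n2 - 1.0) > tol:
        raise InvalidArgumentError(f"quaternion norm² = {n2:.6g}, not unit")
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def quat_from_axis_angle(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0.0:
        if angle_rad == 0.0:
            return quat_identity()
        raise InvalidArgumentError("zero axis with non-zero angle")
    half = 0.5 * angle_rad
    s = math.sin(half) / n
    return np.array([math.cos(half), axis[0] * s, axis[1] * s, axis[2] * s])


def rotate_vector(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Apply the rotation: sensor frame -> global frame."""
    w, x, y, z = q
    vx, vy, vz = v
    # q v q* expanded (cheaper than building the matrix)
    tx = 2.0 * (y * vz - z * vy)
    ty = 2.0 * (z * vx - x * vz)
    tz = 2.0 * (x * vy - y * vx)
    return np.array(
        [
            vx + w * tx + (y * tz - z * ty),
            vy + w * ty + (z * tx - x * tz),
            vz + w * tz + (x * ty - y * tx),
        ]
    )


def rotate_vector_inverse(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Apply the inverse rotation: global frame -> sensor frame."""
    w, x, y, z = q
    vx, vy, vz = v
    tx = 2.0 * (z * vy - y * vz)
    ty = 2.0 * (x * vz - z * vx)
    tz = 2.0 * (y * vx - x * vy)
    return np.array(
        [
            vx + w * tx + (z * ty - y * tz),
            vy + w * ty + (x * tz - z * tx),
            vz + w * tz + (y * tx - x * ty),
        ]
    )


def integrate_quat(q: np.ndarray, omega: np.ndarray, dt: float) -> np.ndarray:
    """First-order strapdown update ``q + (dt/2) q ⊗ (0, ω)``, renormalized.

    ``omega`` is the body-frame angular rate in rad/s.  Per-step error is
    O((‖ω‖ dt)³) in angle after renormalization, negligible at 200 Hz gait
    rates.
    """
    if not dt > 0.0:
        raise InvalidArgumentError(f"dt must be positive, got {dt}")
    w, x, y, z = q
    ox, oy, oz = omega
    h = 0.5 * dt
    qn = np.array(
        [
            w + h * (-x * ox - y * oy - z * oz),
            x + h * (w * ox + y * oz - z * oy),
            y + h * (w * oy - x * oz + z * ox),
            z + h * (w * oz + x * oy - y * ox),
        ]
    )
    return normalize(qn)


def euler_zyx(q: np.ndarray, *, sample_index: int | None = None) -> tuple[float, float, float]:
    """Z–Y–X Euler decomposition, returned as (yaw, pitch, roll) in degrees.

    ``R(q) = Rz(yaw) @ Ry(pitch) @ Rx(roll)``.  Under the global frame used
    here (X mediolateral, Y vertical, Z anteroposterior) the roll component
    (about X) is the sagittal-plane angle
    ``atan2(2(q0 q1 + q2 q3), 1 − 2(q1² + q2²))`` and the pitch component
    (about the vertical Y axis) is the transverse-plane angle.

    Raises :class:`DegenerateOrientationError` when pitch is within 0.5° of
    ±90° (gimbal lock).
    """
    q = normalize(np.asarray(q, dtype=float))
    w, x, y, z = q
    sin_pitch = 2.0 * (w * y - z * x)
    sin_pitch = min(1.0, max(-1.0, sin_pitch))
    pitch = math.asin(sin_pitch)
    if 90.0 - abs(math.degrees(pitch)) < _GIMBAL_GUARD_DEG:
        raise DegenerateOrientationError(
            f"pitch {math.degrees(pitch):.3f}° within gimbal guard", sample_index
        )
    roll = math.atan2(2.0 * (w * x + y * z), 1.0 - 2.0 * (x * x + y * y))
    yaw = math.atan2(2.0 * (w * z + x * y), 1.0 - 2.0 * (y * y + z * z))
    return math.degrees(yaw), math.degrees(pitch), math.degrees(roll)


def quat_from_euler_zyx(yaw_deg: float, pitch_deg: float, roll_deg: float) -> np.ndarray:
    """Inverse of :func:`euler_zyx`."""
    qz = quat_from_axis_angle(np.array([0.0, 0.0, 1.0]), math.radians(yaw_deg))
    qy = quat_from_axis_angle(np.array([0.0, 1.0, 0.0]), math.radians(pitch_deg))
    qx = quat_from_axis_angle(np.array([1.0, 0.0, 0.0]), math.radians(roll_deg))
    return quat_multiply(quat_multiply(qz, qy), qx)


def quat_from_matrix(r: np.ndarray) -> np.ndarray:
    """Unit quaternion (canonical, w >= 0) from a rotation matrix (Shepperd's method)."""
    r = np.asarray(r, dtype=float)
    tr = r[0, 0] + r[1, 1] + r[2, 2]
    if tr > 0:
        s = math.sqrt(tr + 1.0) * 2.0
        q = np.array(
            [0.25 * s, (r[2, 1] - r[1, 2]) / s, (r[0, 2] - r[2, 0]) / s, (r[1, 0] - r[0, 1]) / s]
        )
    else:
        i = int(np.argmax([r[0, 0], r[1, 1], r[2, 2]]))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = math.sqrt(max(1.0 + r[i, i] - r[j, j] - r[k, k], 0.0)) * 2.0
        q = np.empty(4)
        q[0] = (r[k, j] - r[j, k]) / s
        q[1 + i] = 0.25 * s
        q[1 + j] = (r[j, i] + r[i, j]) / s
        q[1 + k] = (r[k, i] + r[i, k]) / s
    return canonical(q)


def quat_angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    """Geodesic angle in degrees between two rotations.

    Uses the chord ‖a ∓ b‖ rather than acos of the dot product, which keeps
    full precision for very small angles.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = min(float(np.linalg.norm(a - b)), float(np.linalg.norm(a + b)))
    return math.degrees(4.0 * math.asin(min(1.0, 0.5 * d)))
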