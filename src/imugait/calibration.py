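"""Sensor-level calibration and sensor-to-segment alignment.

Four procedures, all run before a walking trial:

* gyroscope zero-bias estimation from a static interval,
* classic six-position accelerometer calibration (per-axis scale + bias),
* ellipsoid-based magnetometer calibration (hard-iron offset + symmetric
  soft-iron correction),
* neutral-standing sensor-to-segment alignment.

The anatomical neutral is defined so that every segment frame coincides with
the global frame during quiet standing; the alignment quaternion of a node is
therefore the inverse of its converged static orientation, and all joint and
pelvic angles are zero at calibration by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from . import quat
from .errors import (
    DegenerateCalibrationError,
    DegenerateFitError,
    InvalidArgumentError,
    NotStaticError,
    UnstableNeutralError,
)
from .frames import GRAVITY

__all__ = [
    "AccelCalibration",
    "MagCalibration",
    "SegmentAlignment",
    "estimate_gyro_bias",
    "calibrate_accel_six_position",
    "calibrate_mag_ellipsoid",
    "compute_neutral_alignment",
    "SIX_POSITION_ORDER",
]

#: Expected orientation order of the six static positions: the listed sensor
#: axis points up (reads +g), so e.g. position 0 is "+X up".
SIX_POSITION_ORDER = ("+x", "-x", "+y", "-y", "+z", "-z")


@dataclass
class AccelCalibration:
    """Per-axis accelerometer scale factors (dimensionless) and biases (m/s²)."""

    scale: np.ndarray
    bias: np.ndarray

    def apply(self, accel: np.ndarray) -> np.ndarray:
        return (np.asarray(accel, dtype=float) - self.bias) / self.scale

    @classmethod
    def identity(cls) -> "AccelCalibration":
        return cls(np.ones(3), np.zeros(3))


@dataclass
class MagCalibration:
    """Hard-iron offset and symmetric positive-definite soft-iron correction.

    ``apply`` maps raw samples onto (approximately) the unit sphere:
    ``m_cal = soft_iron @ (m - offset)``.
    """

    offset: np.ndarray
    soft_iron: np.ndarray

    def apply(self, mag: np.ndarray) -> np.ndarray:
        m = np.asarray(mag, dtype=float)
        return (m - self.offset) @ self.soft_iron.T

    @classmethod
    def identity(cls) -> "MagCalibration":
        return cls(np.zeros(3), np.eye(3))


@dataclass
class SegmentAlignment:
    """Per-node quaternion mapping the segment frame into the sensor frame.

    Composing a sensor orientation with the alignment,
    ``q_segment = q_sensor ⊗ q_align``, yields the anatomical segment
    orientation; at the neutral capture this composition is the identity.
    """

    quaternion: np.ndarray
    placement: str
    timestamp: float = 0.0

    @classmethod
    def identity(cls, placement: str) -> "SegmentAlignment":
        return cls(quat.quat_identity(), placement)


def estimate_gyro_bias(
    static_gyro: np.ndarray,
    fs: float = 200.0,
    *,
    std_threshold: float = 0.05,
) -> np.ndarray:
    """Per-axis mean angular rate over a static interval (the constant bias b).

    The interval must span at least one second and pass a variance test:
    per-axis standard deviation below ``std_threshold`` rad/s (the mean is
    deliberately not tested — it *is* the bias being estimated).
    """
    g = np.asarray(static_gyro, dtype=float)
    if g.ndim != 2 or g.shape[1] != 3:
        raise InvalidArgumentError("static_gyro must be (n, 3)")
    if g.shape[0] < fs:
        raise NotStaticError(f"need >= 1 s of static samples, got {g.shape[0] / fs:.2f} s")
    stds = g.std(axis=0)
    if np.any(stds > std_threshold):
        raise NotStaticError(
            f"angular-rate std {stds} rad/s exceeds static threshold {std_threshold}"
        )
    return g.mean(axis=0)


def calibrate_accel_six_position(six_static_means: np.ndarray) -> AccelCalibration:
    """Least-squares per-axis scale and bias from six ±g static positions.

    ``six_static_means`` is (6, 3), ordered per :data:`SIX_POSITION_ORDER`.
    The model per axis i is ``measured = scale_i * true + bias_i`` with the
    true reading ±g when axis i is vertical and 0 otherwise.
    """
    m = np.asarray(six_static_means, dtype=float)
    if m.shape != (6, 3):
        raise InvalidArgumentError("six_static_means must be (6, 3)")
    # duplicated positions make the per-axis design rank-deficient
    if len({tuple(np.round(row, 12)) for row in m}) < 6:
        raise DegenerateCalibrationError("two static positions are identical")
    truth = np.zeros((6, 3))
    for j, label in enumerate(SIX_POSITION_ORDER):
        axis = "xyz".index(label[1])
        truth[j, axis] = GRAVITY if label[0] == "+" else -GRAVITY
    scale = np.empty(3)
    bias = np.empty(3)
    for i in range(3):
        design = np.column_stack([truth[:, i], np.ones(6)])
        sol, _, rank, _ = np.linalg.lstsq(design, m[:, i], rcond=None)
        if rank < 2:
            raise DegenerateCalibrationError(f"degenerate design for axis {'xyz'[i]}")
        scale[i], bias[i] = sol
    if np.any(scale <= 0.5) or np.any(scale >= 2.0):
        raise DegenerateCalibrationError(f"implausible scale factors {scale}")
    return AccelCalibration(scale, bias)


def calibrate_mag_ellipsoid(samples: np.ndarray) -> MagCalibration:
    """Algebraic least-squares ellipsoid fit for hard/soft-iron compensation.

    Fits the general quadric ``xᵀAx + 2bᵀx = 1`` (9 parameters), recovers the
    centre (hard-iron offset) and the symmetric square root of the normalized
    shape matrix (soft-iron correction) so corrected samples lie on the unit
    sphere.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3 or x.shape[0] < 9:
        raise DegenerateFitError("need >= 9 well-distributed 3-D samples")
    d = np.column_stack(
        [
            x[:, 0] ** 2,
            x[:, 1] ** 2,
            x[:, 2] ** 2,
            2 * x[:, 0] * x[:, 1],
            2 * x[:, 0] * x[:, 2],
            2 * x[:, 1] * x[:, 2],
            2 * x[:, 0],
            2 * x[:, 1],
            2 * x[:, 2],
        ]
    )
    if np.linalg.cond(d) > 1e10:
        raise DegenerateFitError("sample distribution is degenerate (coplanar or clustered)")
    p, *_ = np.linalg.lstsq(d, np.ones(x.shape[0]), rcond=None)
    a = np.array(
        [
            [p[0], p[3], p[4]],
            [p[3], p[1], p[5]],
            [p[4], p[5], p[2]],
        ]
    )
    b = p[6:9]
    eigvals = np.linalg.eigvalsh(a)
    if np.any(eigvals <= 0):
        raise DegenerateFitError("fitted quadric is not an ellipsoid")
    center = -np.linalg.solve(a, b)
    # (x - c)ᵀ A (x - c) = 1 + bᵀ A⁻¹ b  =>  normalize the shape matrix
    radius2 = 1.0 + float(b @ np.linalg.solve(a, b))
    if radius2 <= 0:
        raise DegenerateFitError("fitted quadric has no real surface")
    shape = a / radius2
    soft_iron = scipy.linalg.sqrtm(shape).real
    soft_iron = 0.5 * (soft_iron + soft_iron.T)
    return MagCalibration(center, soft_iron)


def compute_neutral_alignment(
    q_sensor_static: np.ndarray,
    placement: str,
    fs: float = 200.0,
    *,
    convergence_deg: float = 0.5,
    timestamp: float = 0.0,
) -> SegmentAlignment:
    """Sensor-to-segment alignment from the neutral-standing capture.

    Accepts either a single converged sensor orientation (shape ``(4,)``) or
    an orientation series (shape ``(n, 4)``), in which case the change over
    the final 0.5 s must be below ``convergence_deg`` degrees.
    """
    q = np.asarray(q_sensor_static, dtype=float)
    if q.ndim == 2:
        tail = max(4, int(round(0.5 * fs)))
        if q.shape[0] < tail:
            raise UnstableNeutralError("static capture shorter than the convergence window")
        win = np.array(q[-tail:], copy=True)
        # hemisphere-align, then average halves: the convergence test measures
        # systematic drift over the window, not per-sample noise jitter
        win[win @ win[0] < 0] *= -1.0
        qa = quat.normalize(win[: tail // 2].mean(axis=0))
        qb = quat.normalize(win[tail // 2 :].mean(axis=0))
        drift = quat.quat_angle_deg(qa, qb)
        if drift > convergence_deg:
            raise UnstableNeutralError(
                f"orientation drifted {drift:.3f}° over final 0.5 s (limit {convergence_deg}°)"
            )
        q = quat.normalize(win.mean(axis=0))
    q = quat.canonical(q)
    return SegmentAlignment(quat.quat_conjugate(q), placement, timestamp)
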