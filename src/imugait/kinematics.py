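"""Clinical joint and pelvic angles from segment orientations.

Segment orientations are sensor orientations composed with the neutral
sensor-to-segment alignments.  The joint rotation is the distal segment
expressed relative to the proximal one, ``q_joint = q_prox⁻¹ ⊗ q_dist``,
decomposed in a Z–Y–X Euler sequence.  Under the frame convention used here
the about-X component is the sagittal-plane angle and the about-Y (vertical)
component the transverse-plane angle; clinical signs (flexion +,
dorsiflexion +, anterior tilt +) are applied via :data:`frames.SAGITTAL_SIGN`.

All three planes are always emitted, even though only the sagittal and
pelvic components carry validated meaning — Euler decompositions couple the
planes, and hiding the cross-talk would not remove it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import quat
from .calibration import SegmentAlignment
from .errors import DegenerateOrientationError, InsufficientCyclesError
from .events import GaitCycle
from .frames import clinical_sign

__all__ = [
    "JointAngleSeries",
    "PelvicAngleSeries",
    "joint_angle_series",
    "pelvic_angle_series",
    "cycle_rom",
    "segment_orientations",
]

_GIMBAL_GUARD_SIN = np.sin(np.radians(89.5))


@dataclass
class JointAngleSeries:
    joint: str
    time: np.ndarray
    sagittal_deg: np.ndarray
    frontal_deg: np.ndarray
    transverse_deg: np.ndarray


@dataclass
class PelvicAngleSeries:
    time: np.ndarray
    tilt_deg: np.ndarray  # anterior tilt positive
    rotation_deg: np.ndarray  # transverse-plane rotation


def _euler_zyx_many(q: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Z–Y–X decomposition: (yaw, pitch, roll) in degrees."""
    w, x, y, z = q.T
    sin_pitch = np.clip(2.0 * (w * y - z * x), -1.0, 1.0)
    bad = np.abs(sin_pitch) > _GIMBAL_GUARD_SIN
    if np.any(bad):
        raise DegenerateOrientationError(
            "pitch within 0.5° of ±90°", int(np.flatnonzero(bad)[0])
        )
    pitch = np.arcsin(sin_pitch)
    roll = np.arctan2(2.0 * (w * x + y * z), 1.0 - 2.0 * (x * x + y * y))
    yaw = np.arctan2(2.0 * (w * z + x * y), 1.0 - 2.0 * (y * y + z * z))
    return np.degrees(yaw), np.degrees(pitch), np.degrees(roll)


def _compose_many(qa: np.ndarray, qb: np.ndarray) -> np.ndarray:
    """Row-wise Hamilton product of (n, 4) arrays (or one broadcastable (4,))."""
    qa = np.atleast_2d(qa)
    qb = np.atleast_2d(qb)
    aw, ax, ay, az = qa.T
    bw, bx, by, bz = qb.T
    return np.column_stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ]
    )


def _conjugate_many(q: np.ndarray) -> np.ndarray:
    out = np.array(q, dtype=float, copy=True)
    out[:, 1:] *= -1.0
    return out


def segment_orientations(q_sensor: np.ndarray, alignment: SegmentAlignment) -> np.ndarray:
    """Anatomical segment orientation series: ``q_seg = q_sensor ⊗ q_align``."""
    return _compose_many(np.asarray(q_sensor, dtype=float), alignment.quaternion)


def joint_angle_series(
    q_prox: np.ndarray,
    q_dist: np.ndarray,
    align_prox: SegmentAlignment,
    align_dist: SegmentAlignment,
    joint: str,
    time: np.ndarray | None = None,
) -> JointAngleSeries:
    """Three-plane joint angles of ``q_prox⁻¹ ⊗ q_dist`` with clinical signs.

    The sagittal series is unwrapped to remove ±360° jumps; the frontal and
    transverse series are reported raw.
    """
    qp = segment_orientations(q_prox, align_prox)
    qd = segment_orientations(q_dist, align_dist)
    qj = _compose_many(_conjugate_many(qp), qd)
    yaw, pitch, roll = _euler_zyx_many(qj)
    sagittal = clinical_sign(joint) * np.degrees(np.unwrap(np.radians(roll)))
    t = np.arange(qj.shape[0], dtype=float) if time is None else np.asarray(time, dtype=float)
    return JointAngleSeries(joint, t, sagittal, yaw, pitch)


def pelvic_angle_series(
    q_pelvis: np.ndarray,
    alignment: SegmentAlignment,
    time: np.ndarray | None = None,
) -> PelvicAngleSeries:
    """Pelvic tilt (sagittal) and rotation (transverse) relative to global."""
    qs = segment_orientations(q_pelvis, alignment)
    _, pitch, roll = _euler_zyx_many(qs)
    tilt = clinical_sign("pelvic_tilt") * np.degrees(np.unwrap(np.radians(roll)))
    t = np.arange(qs.shape[0], dtype=float) if time is None else np.asarray(time, dtype=float)
    return PelvicAngleSeries(t, tilt, pitch)


def cycle_rom(
    time: np.ndarray,
    series: np.ndarray,
    cycles: list[GaitCycle],
    *,
    side: str | None = None,
) -> tuple[list[float], float]:
    """Per-cycle range of motion and the trial-mean scalar.

    ROM = max − min of the angle within each *stable* cycle; the trial scalar
    (the unit of the trial-level agreement analysis) is the arithmetic mean
    over stable cycles.
    """
    t = np.asarray(time, dtype=float)
    s = np.asarray(series, dtype=float)
    roms: list[float] = []
    for cyc in cycles:
        if not cyc.stable or (side is not None and cyc.side != side):
            continue
        i0, i1 = np.searchsorted(t, cyc.start), np.searchsorted(t, cyc.end)
        if i1 - i0 < 2:
            continue
        seg = s[i0:i1]
        roms.append(float(seg.max() - seg.min()))
    if not roms:
        raise InsufficientCyclesError("no stable cycles with data")
    return roms, float(np.mean(roms))
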