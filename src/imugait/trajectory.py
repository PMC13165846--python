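"""ZUPT-corrected foot trajectory reconstruction and spatiotemporal parameters.

The measured specific force is rotated into the global frame with the
estimated orientation, gravity is restored, and the linear acceleration is
integrated (trapezoidal) to velocity.  The zero-velocity assumption is
imposed only at the midpoints of detected foot-flat intervals: between
consecutive midpoints the linear drift ramp that zeroes velocity at both
anchors is subtracted before the corrected velocity is integrated to
position.  Spatiotemporal parameters follow from the positions at the
initial-contact samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import InsufficientStridesError, InvalidArgumentError
from .events import GaitEvent
from .frames import GRAVITY

__all__ = [
    "FootTrajectory",
    "SpatioTemporal",
    "detect_foot_flat",
    "reconstruct_trajectory",
    "spatiotemporal_params",
]

#: guard excluding impact and push-off transients from the stance window (s)
FOOT_FLAT_GUARD_S = 0.05
#: minimum sustained quiet duration (s)
FOOT_FLAT_MIN_S = 0.05
#: angular-rate quiet threshold (rad/s), 20 °/s
FOOT_FLAT_GYRO_THRESH = math.radians(20.0)
#: |‖a‖ − g| quiet threshold (m/s²)
FOOT_FLAT_ACCEL_THRESH = 0.5


@dataclass
class FootTrajectory:
    side: str
    time: np.ndarray
    velocity: np.ndarray  # (n, 3) global frame, m/s
    position: np.ndarray  # (n, 3) global frame, m
    foot_flat: list[tuple[float, float]]
    zupt_applied: bool


@dataclass
class SpatioTemporal:
    """Trial-level spatiotemporal gait parameters (per side and trial means)."""

    stride_length_m: float
    stride_length_by_side: dict
    step_width_m: float
    cadence_spm: float
    velocity_ms: float
    cycle_duration_s: float
    stride_lengths: dict  # side -> per-stride list
    n_steps: int


def detect_foot_flat(
    time: np.ndarray,
    gyro: np.ndarray,
    accel: np.ndarray,
    events: list[GaitEvent],
    *,
    side: str | None = None,
    include_trial_edges: bool = True,
) -> tuple[list[tuple[float, float]], int]:
    """Quiet foot-flat intervals inside each stance phase.

    Within each guarded stance window [HS+50 ms, TO−50 ms] the longest
    contiguous run with ‖ω‖ < 20 °/s and |‖a‖ − g| < 0.5 m/s² sustained for
    at least 50 ms is kept.  The sensor-frame norms are used, so the test is
    independent of mounting.  The static stand before the first toe-off and
    after the last heel strike are included as stance-like windows when
    ``include_trial_edges`` is set (the trial protocol starts and ends
    standing).

    Returns ``(intervals, n_missing)`` where ``n_missing`` counts stance
    phases with no qualifying interval (those strides are excluded from the
    spatial parameters downstream).
    """
    t = np.asarray(time, dtype=float)
    w = np.linalg.norm(np.asarray(gyro, dtype=float), axis=1)
    a = np.abs(np.linalg.norm(np.asarray(accel, dtype=float), axis=1) - GRAVITY)
    quiet = (w < FOOT_FLAT_GYRO_THRESH) & (a < FOOT_FLAT_ACCEL_THRESH)

    ev = sorted(
        (e for e in events if side is None or e.side == side), key=lambda e: e.time
    )
    windows: list[tuple[float, float]] = []
    if include_trial_edges and ev:
        first = ev[0]
        if first.type == "TO":
            windows.append((t[0], first.time - FOOT_FLAT_GUARD_S))
        last = ev[-1]
        if last.type == "HS":
            windows.append((last.time + FOOT_FLAT_GUARD_S, t[-1]))
    for e0, e1 in zip(ev[:-1], ev[1:]):
        if e0.type == "HS" and e1.type == "TO":
            windows.append((e0.time + FOOT_FLAT_GUARD_S, e1.time - FOOT_FLAT_GUARD_S))
    windows.sort()

    fs = 1.0 / np.median(np.diff(t))
    min_len = int(round(FOOT_FLAT_MIN_S * fs))
    intervals: list[tuple[float, float]] = []
    n_missing = 0
    for w0, w1 in windows:
        i0, i1 = np.searchsorted(t, w0), np.searchsorted(t, w1)
        if i1 - i0 < min_len:
            n_missing += 1
            continue
        best = _longest_true_run(quiet[i0:i1])
        if best is None or best[1] - best[0] < min_len:
            n_missing += 1
            continue
        intervals.append((float(t[i0 + best[0]]), float(t[i0 + best[1] - 1])))
    return intervals, n_missing


def _longest_true_run(mask: np.ndarray) -> tuple[int, int] | None:
    """(start, stop) of the longest contiguous True run, or None."""
    if not mask.any():
        return None
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, stops = edges[::2], edges[1::2]
    k = int(np.argmax(stops - starts))
    return int(starts[k]), int(stops[k])


def reconstruct_trajectory(
    time: np.ndarray,
    specific_force: np.ndarray,
    orientations: np.ndarray,
    intervals: list[tuple[float, float]],
    *,
    side: str = "r",
) -> FootTrajectory:
    """Strapdown double integration with ZUPT linear de-drifting.

    When ``intervals`` is empty the uncorrected trajectory is returned with
    ``zupt_applied=False`` so the caller can refuse to trust it.
    """
    t = np.asarray(time, dtype=float)
    f = np.asarray(specific_force, dtype=float)
    q = np.asarray(orientations, dtype=float)
    if not (t.shape[0] == f.shape[0] == q.shape[0]):
        raise InvalidArgumentError("time, specific force, and orientation lengths differ")

    w, x, y, z = q.T
    fx, fy, fz = f.T
    # a_lin = R(q) f + g_vec (global frame, gravity restored then removed)
    ax = (1 - 2 * (y * y + z * z)) * fx + 2 * (x * y - w * z) * fy + 2 * (x * z + w * y) * fz
    ay = 2 * (x * y + w * z) * fx + (1 - 2 * (x * x + z * z)) * fy + 2 * (y * z - w * x) * fz
    az = 2 * (x * z - w * y) * fx + 2 * (y * z + w * x) * fy + (1 - 2 * (x * x + y * y)) * fz
    a_lin = np.column_stack([ax, ay - GRAVITY, az])

    vel = cumulative_trapezoid(a_lin, t, axis=0, initial=0.0)
    zupt = bool(intervals)
    if zupt:
        anchors = np.array(
            [np.searchsorted(t, 0.5 * (i0 + i1)) for i0, i1 in intervals], dtype=int
        )
        anchors = np.clip(anchors, 0, t.size - 1)
        # integration starts from rest (the protocol begins standing), so the
        # trial start is itself a zero-velocity anchor
        anchors = np.unique(np.concatenate([[0], anchors]))
        # piecewise-linear drift model through the anchor velocities; after
        # the last anchor the drift rate of the final segment is extrapolated
        drift = np.column_stack(
            [np.interp(t, t[anchors], vel[anchors, i]) for i in range(3)]
        )
        last = anchors[-1]
        if anchors.size >= 2 and last < t.size - 1:
            prev = anchors[-2]
            slope = (vel[last] - vel[prev]) / (t[last] - t[prev])
            tail = t[last + 1 :] - t[last]
            drift[last + 1 :] = vel[last] + tail[:, None] * slope
        vel = vel - drift
        vel[anchors] = 0.0  # exact zero at the anchors
    pos = cumulative_trapezoid(vel, t, axis=0, initial=0.0)
    return FootTrajectory(side, t, vel, pos, list(intervals), zupt)


def initial_contact_positions(
    traj: FootTrajectory, events: list[GaitEvent]
) -> tuple[np.ndarray, np.ndarray]:
    """(times, positions) of this side's heel strikes on the reconstructed path."""
    hs = [e for e in events if e.side == traj.side and e.type == "HS"]
    idx = [int(np.clip(np.searchsorted(traj.time, e.time), 0, traj.time.size - 1)) for e in hs]
    return np.array([e.time for e in hs]), traj.position[idx]


def spatiotemporal_params(
    left: FootTrajectory,
    right: FootTrajectory,
    events: list[GaitEvent],
    *,
    stride_variant: str = "projection",
) -> SpatioTemporal:
    """Stride length, step width, cadence, and walking velocity.

    The walking axis is the principal horizontal direction of all contact
    positions; stride length is the displacement between successive same-side
    initial contacts projected on that axis (``stride_variant="euclidean"``
    uses the full 3-D displacement norm instead); step width is the
    contralateral contact separation along the mediolateral axis; cadence
    counts steps of both feet; velocity is the net walking-axis displacement
    over elapsed time between the first and last contact.
    """
    tl, pl = initial_contact_positions(left, events)
    tr, pr = initial_contact_positions(right, events)
    if len(tl) < 2 or len(tr) < 2:
        raise InsufficientStridesError(
            f"need >= 2 initial contacts per side, got L={len(tl)}, R={len(tr)}"
        )
    all_p = np.vstack([pl, pr])
    all_t = np.concatenate([tl, tr])
    order = np.argsort(all_t)
    all_p, all_t = all_p[order], all_t[order]

    horiz = all_p[:, [0, 2]]  # (X mediolateral, Z anteroposterior)
    centered = horiz - horiz.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis2 = vt[0]
    net = horiz[-1] - horiz[0]
    if float(net @ axis2) < 0:
        axis2 = -axis2
    walk_axis = np.array([axis2[0], 0.0, axis2[1]])
    ml_axis = np.array([axis2[1], 0.0, -axis2[0]])  # horizontal perpendicular

    def strides(p: np.ndarray) -> np.ndarray:
        d = np.diff(p, axis=0)
        if stride_variant == "euclidean":
            return np.linalg.norm(d, axis=1)
        return d @ walk_axis

    sl = {"l": strides(pl), "r": strides(pr)}
    sl_mean = {s: float(np.mean(v)) for s, v in sl.items()}

    # pair each left contact with the nearest-in-time right contact
    widths = []
    for t0, p0 in zip(tl, pl):
        j = int(np.argmin(np.abs(tr - t0)))
        widths.append(abs(float((p0 - pr[j]) @ ml_axis)))
    step_width = float(np.mean(widths))

    n_step = all_t.size
    cadence = (n_step - 1) / (all_t[-1] - all_t[0]) * 60.0
    velocity = float((all_p[-1] - all_p[0]) @ walk_axis) / (all_t[-1] - all_t[0])
    cycle_dur = float(np.mean(np.concatenate([np.diff(tl), np.diff(tr)])))
    return SpatioTemporal(
        stride_length_m=float(np.mean(np.concatenate([sl["l"], sl["r"]]))),
        stride_length_by_side=sl_mean,
        step_width_m=step_width,
        cadence_spm=float(cadence),
        velocity_ms=velocity,
        cycle_duration_s=cycle_dur,
        stride_lengths={s: v.tolist() for s, v in sl.items()},
        n_steps=n_step,
    )
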