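"""Heel-strike / toe-off detection from the foot-mounted nodes.

Detection is a dual-feature conjunction: a candidate heel strike (HS) is a
local maximum of global-frame vertical acceleration above an individualized
peak threshold, confirmed by a downward zero crossing of the foot's sagittal
angular velocity within ±50 ms; a toe off (TO) is a local minimum below the
valley threshold confirmed by an upward zero crossing.

Thresholds are individualized: the mean peak and valley amplitudes over the
first three stable gait cycles, multiplied by a scaling coefficient of 0.6.
Before initialization a conservative bootstrap threshold of ±2 m/s² is used
solely to find those first cycles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from . import quat
from .errors import InitializationIncompleteError, InvalidArgumentError
from .frames import GRAVITY

__all__ = [
    "ThresholdSet",
    "GaitEvent",
    "GaitCycle",
    "initialize_thresholds",
    "detect_events",
    "detect_events_adaptive",
    "validate_cycles",
    "vertical_acceleration",
    "sagittal_rate",
]

#: ±temporal window (s) for the angular-velocity zero-crossing confirmation.
ZERO_CROSS_WINDOW_S = 0.05
#: minimum separation between extrema of the same kind (s)
MIN_EVENT_SEPARATION_S = 0.3
#: debounce between consecutive opposite-type events: a heel strike and a
#: toe off closer than this cannot both be physiological (stance and swing
#: each last far longer at walking cadences)
MIN_OPPOSITE_SEPARATION_S = 0.15
#: cycle-duration stability tolerance (fraction of previous cycle)
STABILITY_TOL = 0.20


@dataclass
class ThresholdSet:
    """Individualized detection thresholds for one foot."""

    peak: float = 2.0
    valley: float = -2.0
    coefficient: float = 0.6
    n_init_cycles: int = 3
    initialized: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.coefficient <= 1):
            raise InvalidArgumentError("scaling coefficient must be in (0, 1]")
        if self.initialized and not (self.peak > 0 > self.valley):
            raise InvalidArgumentError("initialized thresholds must satisfy peak > 0 > valley")


@dataclass
class GaitEvent:
    type: str  # "HS" | "TO"
    time: float
    side: str  # "l" | "r"
    index: int  # source sample index


@dataclass
class GaitCycle:
    side: str
    start: float  # HS time
    end: float  # next HS time
    to_time: float
    duration: float
    stable: bool


def initialize_thresholds(
    peak_amplitudes,
    valley_amplitudes,
    *,
    coefficient: float = 0.6,
    n_init_cycles: int = 3,
) -> ThresholdSet:
    """Individualized thresholds: 0.6 × signed mean of the first cycles' extrema."""
    peaks = np.asarray(peak_amplitudes, dtype=float)
    valleys = np.asarray(valley_amplitudes, dtype=float)
    if peaks.size < n_init_cycles or valleys.size < n_init_cycles:
        raise InitializationIncompleteError(
            f"need {n_init_cycles} stable cycles of extrema, "
            f"got {peaks.size} peaks / {valleys.size} valleys"
        )
    return ThresholdSet(
        peak=coefficient * float(peaks.mean()),
        valley=coefficient * float(valleys.mean()),
        coefficient=coefficient,
        n_init_cycles=n_init_cycles,
        initialized=True,
    )


def vertical_acceleration(orientations: np.ndarray, specific_force: np.ndarray) -> np.ndarray:
    """Global-frame vertical linear acceleration (gravity removed), m/s².

    Rotates the measured specific force into the global frame with the
    estimated orientation and subtracts the static 1 g reaction, so the
    result is ~0 when the sensor is at rest regardless of mounting.
    """
    q = np.asarray(orientations, dtype=float)
    f = np.asarray(specific_force, dtype=float)
    w, x, y, z = q.T
    fx, fy, fz = f.T
    # second row of R(q) applied to f
    fy_glob = 2 * (x * y + w * z) * fx + (1 - 2 * (x * x + z * z)) * fy + 2 * (y * z - w * x) * fz
    return fy_glob - GRAVITY


def sagittal_rate(gyro: np.ndarray, alignment_q: np.ndarray) -> np.ndarray:
    """Sagittal-plane foot angular rate in the device mounting convention, rad/s.

    The mediolateral (segment-frame X) component of the angular rate is
    extracted via the alignment quaternion and negated: the original foot
    node's sagittal axis points left, so the heel-strike foot slap is a
    negative-going (downward) zero crossing and the push-off reversal just
    after toe off an upward one — the polarities the detector expects.
    """
    g = np.asarray(gyro, dtype=float)
    # segment-frame rate = R(q_align)^T ω_sensor; take the X component
    r = quat.quat_to_matrix(quat.normalize(alignment_q))
    return -(g @ r[:, 0])


def _zero_crossings(series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(series, dtype=float)
    prev, nxt = s[:-1], s[1:]
    down = np.flatnonzero((prev > 0) & (nxt <= 0))
    up = np.flatnonzero((prev < 0) & (nxt >= 0))
    return down, up


def detect_events(
    a_vert: np.ndarray,
    omega_sag: np.ndarray,
    thresholds: ThresholdSet,
    fs: float,
    *,
    side: str = "r",
    time: np.ndarray | None = None,
) -> list[GaitEvent]:
    """Threshold + zero-crossing conjunction detection, alternation enforced.

    Candidates of the same type closer than 0.3 s are pre-thinned by the peak
    finder; candidates violating HS/TO alternation are dropped keeping the
    stronger extremum.
    """
    a = np.asarray(a_vert, dtype=float)
    w = np.asarray(omega_sag, dtype=float)
    if a.shape != w.shape:
        raise InvalidArgumentError("acceleration and angular-velocity series differ in length")
    t = np.arange(a.size) / fs if time is None else np.asarray(time, dtype=float)
    sep = max(1, int(round(MIN_EVENT_SEPARATION_S * fs)))
    win = int(round(ZERO_CROSS_WINDOW_S * fs))

    peaks, _ = find_peaks(a, height=thresholds.peak, distance=sep)
    valleys, _ = find_peaks(-a, height=-thresholds.valley, distance=sep)
    down, up = _zero_crossings(w)

    def confirmed(idx: np.ndarray, crossings: np.ndarray) -> list[int]:
        if crossings.size == 0:
            return []
        return [int(i) for i in idx if np.min(np.abs(crossings - i)) <= win]

    cands = [("HS", i, a[i]) for i in confirmed(peaks, down)]
    cands += [("TO", i, a[i]) for i in confirmed(valleys, up)]
    cands.sort(key=lambda c: c[1])

    kept: list[tuple[str, int, float]] = []
    debounce = MIN_OPPOSITE_SEPARATION_S * fs
    for c in cands:
        while kept and (kept[-1][0] == c[0] or c[1] - kept[-1][1] < debounce):
            # alternation or debounce violated: keep the stronger extremum
            if abs(c[2]) > abs(kept[-1][2]):
                kept.pop()
            else:
                c = None
                break
        if c is not None:
            kept.append(c)
    return [GaitEvent(typ, float(t[i]), side, i) for typ, i, _ in kept]


def validate_cycles(events: list[GaitEvent]) -> list[GaitCycle]:
    """Build HS→TO→next-HS cycles per side and flag physiological stability.

    A cycle is stable when its event ordering is physiological (exactly one
    TO strictly inside the HS pair) and its duration is within ±20% of the
    immediately preceding cycle; the first cycle is provisionally stable.
    Malformed sequences yield unstable flags, never exceptions.
    """
    cycles: list[GaitCycle] = []
    for side in ("l", "r"):
        ev = sorted((e for e in events if e.side == side), key=lambda e: e.time)
        hs = [e for e in ev if e.type == "HS"]
        prev_duration: float | None = None
        for a, b in zip(hs[:-1], hs[1:]):
            inside = [e for e in ev if e.type == "TO" and a.time < e.time < b.time]
            duration = b.time - a.time
            ordered = len(inside) == 1
            to_time = inside[0].time if inside else float("nan")
            stable = ordered and duration > 0
            if stable and prev_duration is not None:
                stable = abs(duration - prev_duration) <= STABILITY_TOL * prev_duration
            cycles.append(GaitCycle(side, a.time, b.time, to_time, duration, stable))
            prev_duration = duration
    cycles.sort(key=lambda c: c.start)
    return cycles


def detect_events_adaptive(
    a_vert: np.ndarray,
    omega_sag: np.ndarray,
    fs: float,
    *,
    side: str = "r",
    time: np.ndarray | None = None,
    coefficient: float = 0.6,
    n_init_cycles: int = 3,
) -> tuple[list[GaitEvent], ThresholdSet]:
    """Bootstrap → individualize → re-detect (batch emulation of the on-line scheme).

    A first pass with conservative ±2 m/s² bootstrap thresholds locates the
    first ``n_init_cycles`` stable cycles; their extremum amplitudes
    individualize the thresholds; a second pass over the full series with the
    individualized thresholds produces the final event list.
    """
    bootstrap = ThresholdSet()
    first = detect_events(a_vert, omega_sag, bootstrap, fs, side=side, time=time)
    cycles = [c for c in validate_cycles(first) if c.stable]
    if len(cycles) < n_init_cycles:
        raise InitializationIncompleteError(
            f"only {len(cycles)} stable bootstrap cycles, need {n_init_cycles}"
        )
    a = np.asarray(a_vert, dtype=float)
    use = cycles[:n_init_cycles]
    peak_amps = []
    valley_amps = []
    for cyc in use:
        for e in first:
            if e.type == "HS" and abs(e.time - cyc.start) < 1e-9:
                peak_amps.append(a[e.index])
            if e.type == "TO" and abs(e.time - cyc.to_time) < 1e-9:
                valley_amps.append(a[e.index])
    thresholds = initialize_thresholds(
        peak_amps, valley_amps, coefficient=coefficient, n_init_cycles=n_init_cycles
    )
    final = detect_events(a_vert, omega_sag, thresholds, fs, side=side, time=time)
    return final, thresholds
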