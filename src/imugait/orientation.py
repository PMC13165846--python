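"""Parameter-adaptive nonlinear complementary filter (NCF) for orientation.

The filter blends gyroscope strapdown integration with gravity and
magnetic-field vector observations through a PI feedback on the composite
cross-product error

    e = â_m × v̂_g + m̂_m × v̂_b,

where ``v̂_g`` and ``v̂_b`` are the global "up" and magnetic reference unit
vectors projected into the sensor frame by the current orientation estimate.
The corrected rate fed to the integrator is

    ω̂ = ω_gyro − b + Kp·e + Ki·∫e dτ.

Two gait-aware adaptations distinguish it from a fixed-gain filter:

* the proportional gain follows ``Kp = Kp0 · exp(−α (‖a‖ − g)²)`` so the
  accelerometer correction is strongest under quasi-static load (‖a‖ ≈ g)
  and nearly vanishes during impact and swing transients, and
* the integral gain switches between a high value during stance (reliable
  gravity reference) and a low value during swing.

Defaults are Kp0 = 1.8, α = 0.5 (s⁴/m², acting on ‖a‖ − g in m/s²),
Ki_high = 0.05, Ki_low = 0.005.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import quat
from .errors import InsufficientDataError, InvalidArgumentError, UnusableSampleError
from .frames import GRAVITY, MAG_REFERENCE, UP

__all__ = [
    "PHASE_UNINITIALIZED",
    "PHASE_STANCE",
    "PHASE_SWING",
    "NcfParams",
    "NcfState",
    "adaptive_kp",
    "select_ki",
    "error_vector",
    "triad_orientation",
    "ncf_step",
    "estimate_orientation",
]

# integer phase codes used in vectorized phase series
PHASE_UNINITIALIZED = 0
PHASE_STANCE = 1
PHASE_SWING = 2

_PHASE_CODES = {
    "uninitialized": PHASE_UNINITIALIZED,
    "stance": PHASE_STANCE,
    "swing": PHASE_SWING,
}


@dataclass
class NcfParams:
    """Filter gains and references.  Defaults are the validated baseline."""

    kp0: float = 1.8
    alpha: float = 0.5
    ki_high: float = 0.05
    ki_low: float = 0.005
    g: float = GRAVITY
    mag_ref: np.ndarray = field(default_factory=lambda: MAG_REFERENCE.copy())
    #: componentwise anti-windup clamp on the integral error
    e_int_clamp: float = 1.0
    #: set True to disable gain scheduling (fixed-gain ablation baseline:
    #: Kp = Kp0 and Ki = Ki_high throughout)
    fixed_gains: bool = False

    def __post_init__(self) -> None:
        if min(self.kp0, self.alpha, self.ki_high, self.ki_low) <= 0:
            raise InvalidArgumentError("all gains must be positive")
        if self.ki_high <= self.ki_low:
            raise InvalidArgumentError("ki_high must exceed ki_low")
        self.mag_ref = np.asarray(self.mag_ref, dtype=float)
        n = np.linalg.norm(self.mag_ref)
        if not np.isclose(n, 1.0, atol=1e-9):
            self.mag_ref = self.mag_ref / n


@dataclass
class NcfState:
    """Mutable filter state: orientation, integral error, gyro bias, phase."""

    q: np.ndarray
    e_int: np.ndarray
    b: np.ndarray
    phase: str = "uninitialized"

    @classmethod
    def initial(cls, q0: np.ndarray | None = None, gyro_bias: np.ndarray | None = None) -> "NcfState":
        return cls(
            q=quat.quat_identity() if q0 is None else np.asarray(q0, dtype=float).copy(),
            e_int=np.zeros(3),
            b=np.zeros(3) if gyro_bias is None else np.asarray(gyro_bias, dtype=float).copy(),
        )


def adaptive_kp(a_mag: float, params: NcfParams) -> float:
    """Acceleration-gated proportional gain ``Kp0 · exp(−α (‖a‖ − g)²)``.

    Equals Kp0 exactly at ``‖a‖ = g`` and decays symmetrically and
    monotonically with the deviation from gravity.
    """
    if a_mag < 0:
        raise InvalidArgumentError("acceleration magnitude must be non-negative")
    if params.fixed_gains:
        return params.kp0
    d = a_mag - params.g
    return params.kp0 * math.exp(-params.alpha * d * d)


def select_ki(phase: str, params: NcfParams) -> float:
    """Phase-scheduled integral gain.

    Stance (and the uninitialized start-up, when the subject is standing
    still) uses the high drift-compensation gain; swing uses the low one.
    """
    if params.fixed_gains:
        return params.ki_high
    code = _PHASE_CODES.get(phase)
    if code is None:
        raise InvalidArgumentError(f"unknown phase {phase!r}")
    return params.ki_low if code == PHASE_SWING else params.ki_high


def error_vector(
    q: np.ndarray, a_meas: np.ndarray, m_meas: np.ndarray, params: NcfParams
) -> np.ndarray:
    """Composite gravity + magnetic cross-product error in the sensor frame."""
    a = np.asarray(a_meas, dtype=float)
    m = np.asarray(m_meas, dtype=float)
    an = np.linalg.norm(a)
    mn = np.linalg.norm(m)
    if an == 0.0 or mn == 0.0:
        raise UnusableSampleError("zero-norm accelerometer or magnetometer sample")
    a = a / an
    m = m / mn
    v_g = quat.rotate_vector_inverse(q, UP)
    v_b = quat.rotate_vector_inverse(q, params.mag_ref)
    return np.cross(a, v_g) + np.cross(m, v_b)


def triad_orientation(accel: np.ndarray, mag: np.ndarray, params: NcfParams) -> np.ndarray:
    """Closed-form static orientation from one accel + mag vector pair (TRIAD).

    Gravity is the trusted primary observation; the magnetometer only fixes
    the rotation about the vertical.
    """
    a = np.asarray(accel, dtype=float)
    m = np.asarray(mag, dtype=float)
    if np.linalg.norm(a) == 0 or np.linalg.norm(m) == 0:
        raise UnusableSampleError("zero-norm initialization vectors")
    s1 = a / np.linalg.norm(a)
    s2 = np.cross(s1, m)
    if np.linalg.norm(s2) < 1e-12:
        raise UnusableSampleError("accelerometer and magnetometer are collinear")
    s2 = s2 / np.linalg.norm(s2)
    s3 = np.cross(s1, s2)
    r1 = UP
    r2 = np.cross(r1, params.mag_ref)
    r2 = r2 / np.linalg.norm(r2)
    r3 = np.cross(r1, r2)
    r = np.column_stack([r1, r2, r3]) @ np.column_stack([s1, s2, s3]).T
    return quat.quat_from_matrix(r)


def ncf_step(
    state: NcfState,
    gyro: np.ndarray,
    accel: np.ndarray,
    mag: np.ndarray,
    dt: float,
    phase: str,
    params: NcfParams,
) -> NcfState:
    """One PI-corrected strapdown update; mutates and returns ``state``.

    A zero-norm accelerometer or magnetometer sample degrades gracefully to a
    gyro-only update (no correction, integral frozen).
    """
    gyro = np.asarray(gyro, dtype=float)
    if not (np.all(np.isfinite(gyro)) and np.isfinite(dt)):
        raise InvalidArgumentError("non-finite gyro sample or dt")
    state.phase = phase
    try:
        e = error_vector(state.q, accel, mag, params)
    except UnusableSampleError:
        omega = gyro - state.b
        state.q = quat.integrate_quat(state.q, omega, dt)
        return state
    c = params.e_int_clamp
    state.e_int = np.clip(state.e_int + e * dt, -c, c)
    kp = adaptive_kp(float(np.linalg.norm(accel)), params)
    ki = select_ki(phase, params)
    omega = gyro - state.b + kp * e + ki * state.e_int
    state.q = quat.integrate_quat(state.q, omega, dt)
    return state


def estimate_orientation(
    time: np.ndarray,
    gyro: np.ndarray,
    accel: np.ndarray,
    mag: np.ndarray,
    params: NcfParams | None = None,
    *,
    phase_codes: np.ndarray | None = None,
    gyro_bias: np.ndarray | None = None,
    init_window_s: float = 1.0,
) -> np.ndarray:
    """Causal batch pass of the NCF over one node's stream.

    The initial orientation is the TRIAD closed form applied to the mean
    accelerometer and magnetometer vectors over the first ``init_window_s``
    seconds (the trial's static stand).  ``phase_codes`` is an optional
    per-sample int array (0 = uninitialized, 1 = stance, 2 = swing) derived
    from the ipsilateral foot's event timeline; when absent the whole stream
    is treated as uninitialized (high integral gain).

    Returns an ``(n, 4)`` array of unit quaternions.
    """
    params = params or NcfParams()
    time = np.asarray(time, dtype=float)
    n = time.size
    if n == 0:
        raise InsufficientDataError("empty stream")
    gyro = np.asarray(gyro, dtype=float)
    accel = np.asarray(accel, dtype=float)
    mag = np.asarray(mag, dtype=float)
    if phase_codes is None:
        phase_codes = np.zeros(n, dtype=np.int8)

    fs_guess = 1.0 / np.median(np.diff(time)) if n > 1 else 200.0
    n_init = max(1, min(n, int(round(init_window_s * fs_guess))))
    q0 = triad_orientation(accel[:n_init].mean(axis=0), mag[:n_init].mean(axis=0), params)

    bias = np.zeros(3) if gyro_bias is None else np.asarray(gyro_bias, dtype=float)
    state = NcfState.initial(q0, bias)
    phase_names = ("uninitialized", "stance", "swing")

    out = np.empty((n, 4))
    out[0] = state.q
    for k in range(1, n):
        dt = time[k] - time[k - 1]
        ncf_step(
            state,
            gyro[k],
            accel[k],
            mag[k],
            dt,
            phase_names[phase_codes[k]],
            params,
        )
        out[k] = state.q
    return out
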