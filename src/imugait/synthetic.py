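"""Ground-truth gait simulator and IMU / reference synthesizer.

The simulator produces a kinematically consistent walking trial for the
seven-node configuration (pelvis, bilateral thighs, shanks, feet):

* periodic sagittal hip and knee waveforms (truncated Fourier series) and
  small pelvic tilt/rotation waveforms drive the orientation chain
  pelvis → thigh → shank; the foot orientation is prescribed directly with
  an exactly flat mid-stance, and the ankle angle is the chain residual;
* each foot's position is piecewise-polynomial: exactly stationary during
  stance, a smooth forward step plus vertical lift during swing, and short
  compact position wiggles whose second derivatives form the heel-strike
  impact peak and toe-off push-off valley in vertical acceleration;
* trials begin and end with quiet standing, with smooth amplitude envelopes
  into and out of steady-state walking, matching a walkway protocol.

Orientations, body-frame angular rates, and foot accelerations are
analytically consistent; proximal-node linear accelerations are obtained by
numerically differentiating the chain positions.  All randomness (noise,
biases, mounting misalignment) flows through a single seeded generator, so
identical seeds give bit-identical streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import quat
from .errors import InfeasibleProfileError
from .events import GaitEvent
from .frames import GRAVITY_VEC, MAG_REFERENCE, PLACEMENTS, SAGITTAL_SIGN
from .io import NodeStream
from .kinematics import _compose_many, _conjugate_many, _euler_zyx_many

__all__ = [
    "GaitProfile",
    "NoiseModel",
    "SyntheticTruth",
    "generate_gait_truth",
    "synthesize_imu",
    "synthesize_reference",
]


# ---------------------------------------------------------------------------
# smooth waveform primitives (value + analytic derivatives)

def _smoothstep(u: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Quintic smoothstep on [0, 1], C² at both ends; clamped outside."""
    u = np.asarray(u, dtype=float)
    c = np.clip(u, 0.0, 1.0)
    inside = (u > 0.0) & (u < 1.0)
    v = 6 * c**5 - 15 * c**4 + 10 * c**3
    d1 = np.where(inside, 30 * c**4 - 60 * c**3 + 30 * c**2, 0.0)
    d2 = np.where(inside, 120 * c**3 - 180 * c**2 + 60 * c, 0.0)
    return v, d1, d2


def _smoothstep3(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cubic smoothstep 3u² − 2u³ on [0, 1]: C¹ at the ends but with
    non-zero curvature there, so junctions between segments produce
    transversal (sharply localized) angular-velocity zero crossings."""
    u = np.asarray(u, dtype=float)
    c = np.clip(u, 0.0, 1.0)
    inside = (u > 0.0) & (u < 1.0)
    v = 3 * c**2 - 2 * c**3
    d1 = np.where(inside, 6 * c - 6 * c**2, 0.0)
    return v, d1


def _bump(u: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit-peak C² bump 64 u³(1−u)³ on [0, 1], zero outside."""
    u = np.asarray(u, dtype=float)
    inside = (u > 0.0) & (u < 1.0)
    c = np.where(inside, u, 0.0)
    v = 64 * c**3 * (1 - c) ** 3
    d1 = 64 * (3 * c**2 * (1 - c) ** 3 - 3 * c**3 * (1 - c) ** 2)
    d2 = 64 * (6 * c * (1 - c) ** 3 - 18 * c**2 * (1 - c) ** 2 + 6 * c**3 * (1 - c))
    return np.where(inside, v, 0.0), np.where(inside, d1, 0.0), np.where(inside, d2, 0.0)


def _pulse(s: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Compact C² pulse cos⁴(πs/2) on [−1, 1]; central curvature −π²."""
    s = np.asarray(s, dtype=float)
    inside = np.abs(s) < 1.0
    x = np.where(inside, 0.5 * np.pi * s, 0.0)
    c, sn = np.cos(x), np.sin(x)
    v = c**4
    d1 = -4 * c**3 * sn * (0.5 * np.pi)
    d2 = (-4) * (c**4 - 3 * c**2 * sn**2) * (0.5 * np.pi) ** 2
    z = np.zeros_like(s)
    return np.where(inside, v, z), np.where(inside, d1, z), np.where(inside, d2, z)


def _fourier(phase: np.ndarray, mean: float, harmonics) -> tuple[np.ndarray, np.ndarray]:
    """Truncated Fourier series of cycle phase; returns (value, d/dφ)."""
    v = np.full_like(np.asarray(phase, dtype=float), mean)
    d = np.zeros_like(v)
    for k, (amp, ph) in enumerate(harmonics, start=1):
        arg = 2 * np.pi * k * phase + ph
        v = v + amp * np.cos(arg)
        d = d - amp * 2 * np.pi * k * np.sin(arg)
    return v, d


class _Envelope:
    """Smooth on/off amplitude envelope with analytic derivative."""

    def __init__(self, t_on: float, ramp_up: float, t_off: float, ramp_down: float):
        self.t_on, self.ru, self.t_off, self.rd = t_on, ramp_up, t_off, ramp_down

    def __call__(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        up, dup, _ = _smoothstep((np.asarray(t) - self.t_on) / self.ru)
        dn, ddn, _ = _smoothstep((np.asarray(t) - self.t_off) / self.rd)
        v = up * (1.0 - dn)
        d = dup / self.ru * (1.0 - dn) - up * ddn / self.rd
        return v, d


# ---------------------------------------------------------------------------
# profile / noise / truth containers

@dataclass
class GaitProfile:
    """Walking conditions of the simulated trial.

    Defaults emulate a healthy adult on a straight walkway at a comfortable
    self-selected speed: cadence 114 steps/min (1.05 s gait cycle), stride
    1.36 m — hence ≈1.29 m/s — for 14 cycles (~15 s of walking) bracketed by
    quiet standing.  Joint waveforms are truncated 3-harmonic Fourier series
    with conventional normal-gait magnitudes (hip ≈ 40° ROM, knee ≈ 60°).
    """

    cadence_spm: float = 114.0
    stride_length_m: float = 1.36
    n_cycles: int = 14
    duty_factor: float = 0.6
    step_width_m: float = 0.10
    fs: float = 200.0
    lead_in_s: float = 2.5
    tail_s: float = 2.0
    # 3-harmonic fits to canonical normal-gait sagittal waveforms
    # (hip ≈ 30° flexion at contact to −10° in late stance; knee ≈ 5° at
    # contact, ~18° loading response, ~62° swing peak)
    hip_mean_deg: float = 14.1
    hip_harmonics: tuple = ((21.4, 0.431), (4.04, -3.018), (1.3, -1.22))
    knee_mean_deg: float = 23.4
    knee_harmonics: tuple = ((21.82, 1.72), (15.88, -2.571), (2.3, -1.639))
    pelvic_tilt_amp_deg: float = 1.5
    pelvic_rot_amp_deg: float = 4.0
    foot_landing_deg: float = 15.0
    foot_swing_peak_deg: float = 55.0
    heel_off_frac: float = 0.42
    foot_flat_start_frac: float = 0.08
    lift_height_m: float = 0.03
    hs_pulse_ms2: float = 14.0
    to_pulse_ms2: float = 12.0
    pulse_halfwidth_s: float = 0.04
    thigh_len_m: float = 0.44
    shank_len_m: float = 0.43
    foot_len_m: float = 0.25
    pelvis_halfwidth_m: float = 0.12
    hip_height_m: float = 0.92
    sensor_frac: float = 0.6  # sensor at middle-to-distal third of the segment
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.5 < self.duty_factor < 0.75):
            raise InfeasibleProfileError(f"duty factor {self.duty_factor} outside (0.5, 0.75)")
        if self.stride_length_m > 2.0 * (self.thigh_len_m + self.shank_len_m):
            raise InfeasibleProfileError(
                f"stride {self.stride_length_m} m infeasible for leg length "
                f"{self.thigh_len_m + self.shank_len_m} m"
            )
        if self.n_cycles < 1 or self.fs <= 0 or self.cadence_spm <= 0:
            raise InfeasibleProfileError("cycle count, fs, and cadence must be positive")

    @property
    def cycle_duration_s(self) -> float:
        return 120.0 / self.cadence_spm  # two steps per gait cycle


@dataclass
class NoiseModel:
    """Sensor imperfection model; all randomness derives from ``seed``.

    Standard deviations are per-sample at 200 Hz.  ``mount_misalign_deg`` is
    the maximum random sensor-to-segment mounting misalignment per node,
    compensated downstream by the neutral-standing alignment; it is kept in
    the noise-free configuration so calibration stays non-trivially
    exercised.
    """

    gyro_sigma: float = 0.005  # rad/s
    gyro_bias: float = 0.01  # rad/s, per-axis uniform in ±
    accel_sigma: float = 0.2  # m/s²
    accel_bias: float = 0.05  # m/s²
    mag_sigma: float = 0.02  # field units (unit-norm field)
    soft_tissue_amp: float = 0.0  # m/s² sinusoidal artefact on accel
    soft_tissue_freq: float = 8.0  # Hz
    mount_misalign_deg: float = 3.0
    seed: int = 0

    @classmethod
    def zero(cls, seed: int = 0) -> "NoiseModel":
        return cls(
            gyro_sigma=0.0,
            gyro_bias=0.0,
            accel_sigma=0.0,
            accel_bias=0.0,
            mag_sigma=0.0,
            soft_tissue_amp=0.0,
            seed=seed,
        )


@dataclass
class SyntheticTruth:
    """Everything the pipeline is later asked to recover."""

    time: np.ndarray
    fs: float
    profile: GaitProfile
    orientations: dict  # placement -> (n, 4)
    body_rates: dict  # placement -> (n, 3) rad/s
    lin_accel: dict  # placement -> (n, 3) global-frame m/s²
    positions: dict  # placement -> (n, 3) m
    velocities: dict  # foot placements -> (n, 3) m/s
    angles: dict  # variable name -> (n,) degrees
    events: list
    foot_flat: dict  # side -> [(start, end)]
    contact_positions: dict  # side -> (n_hs, 3) foot position at each HS


# ---------------------------------------------------------------------------

def _ry_rx_quat(rho: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Vectorized quaternion of R_y(rho) · R_x(psi) (radians)."""
    cy, sy = np.cos(0.5 * rho), np.sin(0.5 * rho)
    cx, sx = np.cos(0.5 * psi), np.sin(0.5 * psi)
    return np.column_stack([cy * cx, cy * sx, sy * cx, -sy * sx])


def _rotate_offset(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """R(q) @ v for an (n, 4) quaternion array and a fixed 3-vector."""
    w, x, y, z = q.T
    vx, vy, vz = v
    return np.column_stack(
        [
            (1 - 2 * (y * y + z * z)) * vx + 2 * (x * y - w * z) * vy + 2 * (x * z + w * y) * vz,
            2 * (x * y + w * z) * vx + (1 - 2 * (x * x + z * z)) * vy + 2 * (y * z - w * x) * vz,
            2 * (x * z - w * y) * vx + 2 * (y * z + w * x) * vy + (1 - 2 * (x * x + y * y)) * vz,
        ]
    )


def _foot_pitch(p: np.ndarray, prof: GaitProfile) -> tuple[np.ndarray, np.ndarray]:
    """Raw foot X-rotation waveform (deg, toes-down positive) and d/dp.

    Physiological rocker sequence over one cycle phase ``p`` (HS at 0):

    * foot slap: the foot lands heel-first, dorsiflexed (−landing angle),
      and rotates flat over the first 8% of the cycle;
    * exactly flat (zero) through mid-stance;
    * heel-off rise to the push-off peak, reached ~26 ms *after* toe off —
      the sign reversal there is the toe-off angular-velocity zero crossing;
    * swing return: falls through mid-swing to the dorsiflexed landing pose,
      bottoming out ~16 ms before the next heel strike — the sign reversal
      there is the heel-strike zero crossing.

    Cubic smoothsteps give non-zero curvature at every junction, so both
    zero crossings are transversal and sharply localized.
    """
    T = prof.cycle_duration_s
    ho = prof.heel_off_frac
    p_flat0 = prof.foot_flat_start_frac
    p_m1 = prof.duty_factor + 0.026 / T  # push-off peak, just after TO
    p_ret = 1.0 - 0.016 / T  # landing-pose minimum, just before HS
    land, peak = prof.foot_landing_deg, prof.foot_swing_peak_deg
    land_slap = max(land - 0.25, 0.0)  # tiny pre-HS recoil so the minimum is interior
    rec = land - land_slap
    v = np.zeros_like(p)
    d = np.zeros_like(p)
    # foot slap: -land_slap -> 0
    u = p / p_flat0
    s, ds = _smoothstep3(u)
    m = p < p_flat0
    v[m] = -land_slap * (1.0 - s[m])
    d[m] = land_slap * ds[m] / p_flat0
    # heel-off rise 0 -> +peak
    u = (p - ho) / (p_m1 - ho)
    s, ds = _smoothstep3(u)
    m = (p >= ho) & (p < p_m1)
    v[m] = peak * s[m]
    d[m] = peak * ds[m] / (p_m1 - ho)
    # swing return +peak -> -land
    u = (p - p_m1) / (p_ret - p_m1)
    s, ds = _smoothstep3(u)
    m = (p >= p_m1) & (p < p_ret)
    v[m] = peak - (peak + land) * s[m]
    d[m] = -(peak + land) * ds[m] / (p_ret - p_m1)
    # small recoil -land -> -land_slap
    u = (p - p_ret) / (1.0 - p_ret)
    s, ds = _smoothstep3(u)
    m = p >= p_ret
    v[m] = -land + rec * s[m]
    d[m] = rec * ds[m] / (1.0 - p_ret)
    return v, d


def generate_gait_truth(profile: GaitProfile | None = None) -> SyntheticTruth:
    """Forward-kinematic walking trial with analytically consistent signals."""
    prof = profile or GaitProfile()
    T = prof.cycle_duration_s
    duty = prof.duty_factor
    t0 = prof.lead_in_s
    offsets = {"r": 0.0, "l": 0.5}
    walk_end = t0 + (prof.n_cycles + 0.5) * T
    t_end = walk_end + prof.tail_s
    n = int(round(t_end * prof.fs)) + 1
    t = np.arange(n) / prof.fs
    dt = 1.0 / prof.fs

    env_p = _Envelope(t0, T, walk_end, 1.0)
    ep, dep = env_p(t)
    phi_r = (t - t0) / T  # right-side linear phase

    # pelvic waveforms (radians)
    tilt_wave = np.sin(4 * np.pi * phi_r)
    dtilt_wave = 4 * np.pi / T * np.cos(4 * np.pi * phi_r)
    rot_wave = np.sin(2 * np.pi * phi_r)
    drot_wave = 2 * np.pi / T * np.cos(2 * np.pi * phi_r)
    tau = np.radians(prof.pelvic_tilt_amp_deg) * ep * tilt_wave
    dtau = np.radians(prof.pelvic_tilt_amp_deg) * (dep * tilt_wave + ep * dtilt_wave)
    rho = np.radians(prof.pelvic_rot_amp_deg) * ep * rot_wave
    drho = np.radians(prof.pelvic_rot_amp_deg) * (dep * rot_wave + ep * drot_wave)

    orientations: dict = {}
    body_rates: dict = {}
    positions: dict = {}
    velocities: dict = {}
    angles: dict = {}
    events: list[GaitEvent] = []
    foot_flat: dict = {}
    contact_positions: dict = {}
    psi: dict = {}
    dpsi: dict = {}
    foot_z: dict = {}

    orientations["pelvis"] = _ry_rx_quat(rho, tau)
    body_rates["pelvis"] = np.column_stack([dtau, drho * np.cos(tau), -drho * np.sin(tau)])
    angles["pelvic_tilt"] = np.degrees(tau) * SAGITTAL_SIGN["pelvic_tilt"]
    angles["pelvic_rotation"] = np.degrees(rho)

    h = prof.pulse_halfwidth_s
    # a profile with no foot motion at all is a static standing capture:
    # no contact events exist and the whole trial is one foot-flat interval
    moving = any(
        v > 0
        for v in (
            prof.stride_length_m,
            prof.lift_height_m,
            prof.foot_landing_deg,
            prof.foot_swing_peak_deg,
            prof.hs_pulse_ms2,
            prof.to_pulse_ms2,
        )
    )
    for side in ("l", "r"):
        off = offsets[side]
        hs_last = t0 + (prof.n_cycles + off) * T
        env_s = _Envelope(t0 + off * T, T, hs_last, 1.0)
        es, des = env_s(t)
        u = phi_r - off
        phase = np.mod(u, 1.0)

        hip_w, dhip_w = _fourier(phase, prof.hip_mean_deg, prof.hip_harmonics)
        knee_w, dknee_w = _fourier(phase, prof.knee_mean_deg, prof.knee_harmonics)
        hip = es * hip_w
        dhip = des * hip_w + es * dhip_w / T
        knee = es * knee_w
        dknee = des * knee_w + es * dknee_w / T
        angles[f"hip_{side}"] = hip.copy()
        angles[f"knee_{side}"] = knee.copy()

        # orientation chain (raw about-X angles, radians)
        s_hip, s_knee = SAGITTAL_SIGN["hip"], SAGITTAL_SIGN["knee"]
        psi_thigh = tau + np.radians(s_hip * hip)
        dpsi_thigh = dtau + np.radians(s_hip * dhip)
        psi_shank = psi_thigh + np.radians(s_knee * knee)
        dpsi_shank = dpsi_thigh + np.radians(s_knee * dknee)
        for seg, ps, dps in (
            (f"thigh_{side}", psi_thigh, dpsi_thigh),
            (f"shank_{side}", psi_shank, dpsi_shank),
        ):
            orientations[seg] = _ry_rx_quat(rho, ps)
            body_rates[seg] = np.column_stack([dps, drho * np.cos(ps), -drho * np.sin(ps)])
        psi[f"thigh_{side}"] = psi_thigh
        psi[f"shank_{side}"] = psi_shank

        # ---- per-cycle amplitude scales (needed by foot pitch and stride)
        kcyc = np.clip(np.floor(u), 0, prof.n_cycles - 1)
        kidx = kcyc.astype(int)
        in_walk = (u >= 0.0) & (u < prof.n_cycles)
        t_mid_swing = t0 + (np.arange(prof.n_cycles) + off + 0.5 * (1 + duty)) * T
        e_k = env_s(t_mid_swing)[0]

        # foot orientation: prescribed, exactly flat through mid-stance
        p = np.where(in_walk, u - kcyc, 0.0)
        # cycle 0 begins from quiet standing (no preceding swing): skip the slap
        p = np.where(in_walk & (kcyc == 0), np.maximum(p, prof.foot_flat_start_frac), p)
        # after the final heel strike the slap plays out, then the foot stays flat
        post = u >= prof.n_cycles
        p = np.where(post, np.minimum(u - prof.n_cycles, 0.3), p)
        active = in_walk | post
        pitch_w, dpitch_w = _foot_pitch(p, prof)
        # The pitch amplitude is constant within each cycle (the slap that
        # opens a cycle inherits the previous swing's scale, keeping the
        # waveform continuous across heel strike).  A per-cycle constant —
        # rather than the continuous envelope — keeps the angular-velocity
        # zero crossings exactly at the waveform junctions.
        e_prev = np.concatenate([[e_k[0]], e_k[:-1]])
        scale = np.where(p < prof.foot_flat_start_frac, e_prev[kidx], e_k[kidx])
        scale = np.where(post, e_k[-1], scale)
        scale = np.where(active, scale, 0.0)
        theta_f = scale * pitch_w
        dtheta_f = scale * dpitch_w / T
        qf = np.zeros((n, 4))
        half = 0.5 * np.radians(theta_f)
        qf[:, 0] = np.cos(half)
        qf[:, 1] = np.sin(half)
        orientations[f"foot_{side}"] = qf
        body_rates[f"foot_{side}"] = np.column_stack(
            [np.radians(dtheta_f), np.zeros(n), np.zeros(n)]
        )

        # ankle = chain residual (shank⁻¹ ⊗ foot), clinical sign applied
        q_ankle = _compose_many(_conjugate_many(orientations[f"shank_{side}"]), qf)
        _, _, roll = _euler_zyx_many(q_ankle)
        angles[f"ankle_{side}"] = SAGITTAL_SIGN["ankle"] * roll

        # ---- foot trajectory: stationary stance, smooth swing, impact wiggles
        x0 = -0.5 * prof.step_width_m if side == "l" else 0.5 * prof.step_width_m
        stride_k = prof.stride_length_m * e_k
        z_stance = np.concatenate([[0.0], np.cumsum(stride_k)])  # position in stance k

        in_swing = in_walk & (p >= duty)
        v_sw = np.where(in_swing, (p - duty) / (1 - duty), 0.0)
        s, ds, d2s = _smoothstep(v_sw)
        zk = np.where(u < 0, 0.0, z_stance[np.clip(kidx + (u >= prof.n_cycles), 0, prof.n_cycles)])
        lk = stride_k[kidx]
        tsw = (1 - duty) * T
        z = np.where(in_swing, zk + lk * s, zk)
        vz = np.where(in_swing, lk * ds / tsw, 0.0)
        az = np.where(in_swing, lk * d2s / tsw**2, 0.0)

        b, db, d2b = _bump(v_sw)
        lift = prof.lift_height_m * e_k[kidx]
        y = np.where(in_swing, lift * b, 0.0)
        vy = np.where(in_swing, lift * db / tsw, 0.0)
        ay = np.where(in_swing, lift * d2b / tsw**2, 0.0)

        # impact transients: compact position wiggles, zero net velocity change
        ev_side: list[GaitEvent] = []
        for k in range(prof.n_cycles):
            t_to = t0 + (k + off + duty) * T
            t_hs = t0 + (k + 1 + off) * T
            amp_to = prof.to_pulse_ms2 * e_k[k] * h**2 / np.pi**2
            amp_hs = prof.hs_pulse_ms2 * e_k[k] * h**2 / np.pi**2
            for t_ev, amp in ((t_to, amp_to), (t_hs, -amp_hs)):
                m = np.abs(t - t_ev) < h
                pv, pd, pdd = _pulse((t[m] - t_ev) / h)
                y[m] += amp * pv
                vy[m] += amp * pd / h
                ay[m] += amp * pdd / h**2
            ev_side.append(GaitEvent("TO", t_to, side, int(round(t_to * prof.fs))))
            ev_side.append(GaitEvent("HS", t_hs, side, int(round(t_hs * prof.fs))))
        if not moving:
            ev_side = []
        events.extend(ev_side)

        positions[f"foot_{side}"] = np.column_stack([np.full(n, x0), y, z])
        velocities[f"foot_{side}"] = np.column_stack([np.zeros(n), vy, vz])
        lin_acc_foot = np.column_stack([np.zeros(n), ay, az])
        foot_z[side] = lin_acc_foot

        # truth foot-flat intervals (position and orientation exactly frozen)
        ho = prof.heel_off_frac
        flat0 = prof.foot_flat_start_frac * T
        if moving:
            intervals = [(0.0, t0 + (off + ho) * T)]
            for k in range(1, prof.n_cycles):
                start = t0 + (k + off) * T
                intervals.append((start + flat0, start + ho * T))
            intervals.append((hs_last + flat0, float(t[-1])))
        else:
            intervals = [(0.0, float(t[-1]))]
        foot_flat[side] = intervals
        hs_times = [e.time for e in ev_side if e.type == "HS"]
        idx = [int(round(ht * prof.fs)) for ht in hs_times]
        contact_positions[side] = positions[f"foot_{side}"][idx]

    # ---- proximal positions from the chain.  The pelvis progresses smoothly
    # (constant mean velocity with a small 2-per-cycle speed oscillation and
    # vertical bob), unlike the feet's stop-and-go stepping.
    from scipy.integrate import cumulative_trapezoid

    v_mean = prof.stride_length_m / T
    v_pelvis = ep * v_mean * (1.0 + 0.08 * np.cos(4 * np.pi * phi_r - 0.8))
    z_pelvis = cumulative_trapezoid(v_pelvis, t, initial=0.0)
    bob_amp = 0.010 if moving else 0.0  # vertical bob only while stepping
    bob = bob_amp * ep * np.cos(4 * np.pi * phi_r)
    p_pelvis = np.column_stack([np.zeros(n), prof.hip_height_m + bob, z_pelvis])
    positions["pelvis"] = p_pelvis
    lin_accel = {}
    for side in ("l", "r"):
        sgn = -1.0 if side == "l" else 1.0
        hip_off = np.array([sgn * prof.pelvis_halfwidth_m, -0.05, 0.0])
        p_hip = p_pelvis + _rotate_offset(orientations["pelvis"], hip_off)
        down_t = np.array([0.0, -prof.sensor_frac * prof.thigh_len_m, 0.0])
        positions[f"thigh_{side}"] = p_hip + _rotate_offset(orientations[f"thigh_{side}"], down_t)
        p_knee = p_hip + _rotate_offset(
            orientations[f"thigh_{side}"], np.array([0.0, -prof.thigh_len_m, 0.0])
        )
        down_s = np.array([0.0, -prof.sensor_frac * prof.shank_len_m, 0.0])
        positions[f"shank_{side}"] = p_knee + _rotate_offset(orientations[f"shank_{side}"], down_s)

    for name in ("pelvis", "thigh_l", "thigh_r", "shank_l", "shank_r"):
        vel = np.gradient(positions[name], dt, axis=0)
        lin_accel[name] = np.gradient(vel, dt, axis=0)
    lin_accel["foot_l"] = foot_z["l"]
    lin_accel["foot_r"] = foot_z["r"]

    events.sort(key=lambda e: e.time)
    return SyntheticTruth(
        time=t,
        fs=prof.fs,
        profile=prof,
        orientations=orientations,
        body_rates=body_rates,
        lin_accel=lin_accel,
        positions=positions,
        velocities=velocities,
        angles=angles,
        events=events,
        foot_flat=foot_flat,
        contact_positions=contact_positions,
    )


def synthesize_imu(truth: SyntheticTruth, noise: NoiseModel | None = None) -> dict:
    """Invert the measurement model: truth kinematics → seven 200 Hz NodeStreams.

    Per node: gyro = body rate in the (misaligned) sensor frame + bias +
    noise; accel = sensor-frame specific force (linear acceleration minus
    gravity) + bias + noise + optional soft-tissue oscillation;
    magnetometer = sensor-frame unit field reference + noise.
    """
    noise = noise or NoiseModel.zero()
    rng = np.random.default_rng(noise.seed)
    t = truth.time
    n = t.size
    streams: dict[str, NodeStream] = {}
    for placement in PLACEMENTS:
        # fixed draw order keeps streams reproducible per seed
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        ang = math.radians(noise.mount_misalign_deg) * rng.uniform()
        q_mount = quat.quat_from_axis_angle(axis, ang)
        r_mount = quat.quat_to_matrix(q_mount)
        gyro_bias = rng.uniform(-1, 1, 3) * noise.gyro_bias
        accel_bias = rng.uniform(-1, 1, 3) * noise.accel_bias
        st_phase = rng.uniform(0, 2 * np.pi)
        st_dir = rng.standard_normal(3)
        st_dir /= np.linalg.norm(st_dir)
        gyro_noise = rng.standard_normal((n, 3)) * noise.gyro_sigma
        accel_noise = rng.standard_normal((n, 3)) * noise.accel_sigma
        mag_noise = rng.standard_normal((n, 3)) * noise.mag_sigma

        q_seg = truth.orientations[placement]
        w, x, y, z = q_seg.T
        a_g = truth.lin_accel[placement] - GRAVITY_VEC  # a_lin − g, global
        # specific force in segment frame: Rᵀ (a_lin − g)
        f_seg = np.empty((n, 3))
        gx, gy, gz = a_g.T
        f_seg[:, 0] = (1 - 2 * (y * y + z * z)) * gx + 2 * (x * y + w * z) * gy + 2 * (x * z - w * y) * gz
        f_seg[:, 1] = 2 * (x * y - w * z) * gx + (1 - 2 * (x * x + z * z)) * gy + 2 * (y * z + w * x) * gz
        f_seg[:, 2] = 2 * (x * z + w * y) * gx + 2 * (y * z - w * x) * gy + (1 - 2 * (x * x + y * y)) * gz

        soft = (
            noise.soft_tissue_amp
            * np.sin(2 * np.pi * noise.soft_tissue_freq * t + st_phase)[:, None]
            * st_dir
        )
        gyro = truth.body_rates[placement] @ r_mount + gyro_bias + gyro_noise
        accel = f_seg @ r_mount + accel_bias + accel_noise + soft

        # magnetometer: global unit reference seen in the sensor frame
        mw, mx_, my_, mz_ = _compose_many(q_seg, q_mount[None, :]).T
        bx, by, bz = MAG_REFERENCE
        mag = np.empty((n, 3))
        mag[:, 0] = (1 - 2 * (my_ * my_ + mz_ * mz_)) * bx + 2 * (mx_ * my_ + mw * mz_) * by + 2 * (mx_ * mz_ - mw * my_) * bz
        mag[:, 1] = 2 * (mx_ * my_ - mw * mz_) * bx + (1 - 2 * (mx_ * mx_ + mz_ * mz_)) * by + 2 * (my_ * mz_ + mw * mx_) * bz
        mag[:, 2] = 2 * (mx_ * mz_ + mw * my_) * bx + 2 * (my_ * mz_ - mw * mx_) * by + (1 - 2 * (mx_ * mx_ + my_ * my_)) * bz
        mag = mag + mag_noise

        streams[placement] = NodeStream(placement, t.copy(), gyro, accel, mag)
    return streams


def synthesize_reference(
    truth: SyntheticTruth,
    marker_noise_deg: float = 0.0,
    lag_s: float = 0.0,
    fs_ref: float = 100.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Optical-capture-style reference: truth angles at 100 Hz, noise, known lag.

    A sample of the reference stream at its own time ``t`` equals the truth
    at ``t − lag_s`` (positive lag: reference delayed relative to the IMU
    stream), which the cross-correlation alignment should recover.
    """
    if abs(lag_s) > 2.0:
        raise InfeasibleProfileError("reference lag must be within ±2 s")
    rng = np.random.default_rng(seed)
    t_ref = np.arange(0.0, truth.time[-1], 1.0 / fs_ref)
    out: dict[str, np.ndarray] = {}
    for name, series in truth.angles.items():
        v = np.interp(t_ref - lag_s, truth.time, series)
        out[name] = v + rng.standard_normal(t_ref.size) * marker_noise_deg
    return t_ref, out
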