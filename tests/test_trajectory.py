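"""ZUPT trajectory reconstruction and spatiotemporal parameters."""

import numpy as np
import pytest

from imugait import quat
from imugait import trajectory as trj
from imugait.errors import InsufficientStridesError
from imugait.events import GaitEvent
from imugait.frames import GRAVITY
from util import stride_errors_pct


def static_inputs(duration=10.0, fs=200.0, bias=(0.0, 0.0, 0.1)):
    t = np.arange(0.0, duration, 1.0 / fs)
    f = np.tile([bias[0], GRAVITY + bias[1], bias[2]], (t.size, 1))
    q = np.tile(quat.quat_identity(), (t.size, 1))
    return t, f, q


class TestZupt:
    def test_bias_drift_cancelled(self):
        """0.1 m/s² accelerometer bias: with ZUPT the stationary foot stays
        within 1 mm; without, displacement grows quadratically (~½at² = 5 m)."""
        t, f, q = static_inputs()
        intervals = [(a, a + 0.3) for a in np.arange(0.5, 9.5, 1.0)]
        with_zupt = trj.reconstruct_trajectory(t, f, q, intervals)
        without = trj.reconstruct_trajectory(t, f, q, [])
        assert np.abs(with_zupt.position[-1]).max() < 1e-3
        assert with_zupt.zupt_applied and not without.zupt_applied
        assert np.abs(without.position[-1]).max() == pytest.approx(
            0.5 * 0.1 * t[-1] ** 2, rel=0.01
        )

    def test_velocity_exactly_zero_at_anchors(self):
        t, f, q = static_inputs()
        intervals = [(a, a + 0.3) for a in np.arange(0.5, 9.5, 1.0)]
        traj = trj.reconstruct_trajectory(t, f, q, intervals)
        for a, b in intervals:
            i = np.searchsorted(t, 0.5 * (a + b))
            assert np.all(traj.velocity[i] == 0.0)

    def test_stride_recovery_on_clean_walk(self, clean_report, default_truth):
        for side in ("l", "r"):
            assert stride_errors_pct(clean_report, default_truth, side).max() < 5.0

    def test_removing_zupt_increases_stride_error(
        self, clean_recording, clean_report, default_truth
    ):
        """Directional ablation: uncorrected integration degrades stride length."""
        side = "r"
        t = clean_report.time
        uncorr = trj.reconstruct_trajectory(
            t,
            _foot_accel(clean_recording, side),
            clean_report.orientations[f"foot_{side}"],
            [],
            side=side,
        )
        corr = clean_report.trajectories[side]
        truth_strides = np.diff(default_truth.contact_positions[side][:, 2])
        hs = [e for e in clean_report.events if e.side == side and e.type == "HS"]
        idx = [np.searchsorted(t, e.time) for e in hs]

        def err(traj):
            pos = traj.position[idx, 2]
            est = np.diff(pos)
            k = min(len(est), len(truth_strides))
            return np.abs(est[:k] - truth_strides[:k]).mean()

        assert err(uncorr) > err(corr)


def _foot_accel(recording, side):
    """The preprocessed specific force the pipeline feeds the integrator."""
    from imugait.calibration import estimate_gyro_bias
    from imugait.preprocess import preprocess_stream

    s = recording.node(f"foot_{side}")
    bias = estimate_gyro_bias(s.gyro[:400], recording.fs)
    return preprocess_stream(s.gyro - bias, s.accel, s.mag)[1]


class TestFootFlat:
    def test_intervals_inside_guarded_stance(self, clean_recording, clean_report):
        for side in ("l", "r"):
            s = clean_recording.node(f"foot_{side}")
            evs = sorted(
                (e for e in clean_report.events if e.side == side), key=lambda e: e.time
            )
            stances = [
                (a.time, b.time)
                for a, b in zip(evs[:-1], evs[1:])
                if a.type == "HS" and b.type == "TO"
            ]
            mid_intervals = [
                iv
                for iv in clean_report.foot_flat[side]
                if any(h <= iv[0] and iv[1] <= t_ for h, t_ in stances)
            ]
            assert mid_intervals, "no mid-trial foot-flat intervals found"
            for i0, i1 in mid_intervals:
                h, t_ = next((h, t_) for h, t_ in stances if h <= i0 and i1 <= t_)
                assert i0 >= h + trj.FOOT_FLAT_GUARD_S - 1e-9
                assert i1 <= t_ - trj.FOOT_FLAT_GUARD_S + 1e-9

    def test_continuously_rotating_foot_has_no_interval(self):
        fs = 200.0
        t = np.arange(0.0, 4.0, 1 / fs)
        gyro = np.tile([1.0, 0.0, 0.0], (t.size, 1))  # 57 °/s, never quiet
        accel = np.tile([0.0, GRAVITY, 0.0], (t.size, 1))
        events = [GaitEvent("HS", 1.0, "r", 200), GaitEvent("TO", 2.0, "r", 400)]
        intervals, missing = trj.detect_foot_flat(
            t, gyro, accel, events, side="r", include_trial_edges=False
        )
        assert intervals == [] and missing == 1


class TestSpatiotemporal:
    @staticmethod
    def walk_trajectories(ic_times_l, ic_z_l, ic_times_r, ic_z_r, width=0.1):
        """Trajectories whose positions interpolate the given contacts."""
        t_end = max(ic_times_l[-1], ic_times_r[-1]) + 1.0
        t = np.arange(0.0, t_end, 0.005)

        def traj(side, times, zs, x):
            pos = np.column_stack(
                [np.full(t.size, x), np.zeros(t.size), np.interp(t, times, zs)]
            )
            return trj.FootTrajectory(side, t, np.zeros((t.size, 3)), pos, [], True)

        left = traj("l", ic_times_l, ic_z_l, -width / 2)
        right = traj("r", ic_times_r, ic_z_r, width / 2)
        events = [GaitEvent("HS", tt, "l", 0) for tt in ic_times_l]
        events += [GaitEvent("HS", tt, "r", 0) for tt in ic_times_r]
        return left, right, events

    def test_stride_length_definition(self):
        left, right, events = self.walk_trajectories(
            [0.5, 1.5, 2.5, 3.5], [0.0, 1.36, 2.72, 4.08], [1.0, 2.0, 3.0], [0.68, 2.04, 3.40]
        )
        st = trj.spatiotemporal_params(left, right, events)
        assert st.stride_length_m == pytest.approx(1.36, abs=1e-9)
        assert st.step_width_m == pytest.approx(0.1, abs=1e-9)

    def test_cadence_arithmetic(self):
        """25 initial contacts spanning 12 s → (25−1)/12·60 = 120 steps/min."""
        times = np.linspace(0.0, 12.0, 25)
        zs = np.linspace(0.0, 8.0, 25)
        left, right, events = self.walk_trajectories(times[::2], zs[::2], times[1::2], zs[1::2])
        st = trj.spatiotemporal_params(left, right, events)
        assert st.n_steps == 25
        assert st.cadence_spm == pytest.approx(120.0)

    def test_velocity_arithmetic(self):
        """ΔZ = 19.5 m over Δt = 15 s → V = 1.30 m/s."""
        times = np.linspace(0.0, 15.0, 27)
        zs = np.linspace(0.0, 19.5, 27)
        left, right, events = self.walk_trajectories(times[::2], zs[::2], times[1::2], zs[1::2])
        st = trj.spatiotemporal_params(left, right, events)
        assert st.velocity_ms == pytest.approx(1.30, abs=1e-9)

    def test_projection_never_exceeds_euclidean(self, clean_report):
        """Cauchy–Schwarz: the walking-axis projection is bounded by the norm,
        with near equality on straight synthetic walking."""
        proj = trj.spatiotemporal_params(
            clean_report.trajectories["l"],
            clean_report.trajectories["r"],
            clean_report.events,
            stride_variant="projection",
        )
        eucl = trj.spatiotemporal_params(
            clean_report.trajectories["l"],
            clean_report.trajectories["r"],
            clean_report.events,
            stride_variant="euclidean",
        )
        assert proj.stride_length_m <= eucl.stride_length_m + 1e-12
        assert proj.stride_length_m == pytest.approx(eucl.stride_length_m, rel=0.01)

    def test_cadence_consistent_with_cycle_duration(self, clean_report):
        st = clean_report.spatiotemporal
        assert st.cadence_spm == pytest.approx(120.0 / st.cycle_duration_s, rel=0.05)

    def test_insufficient_strides_signal(self):
        left, right, events = self.walk_trajectories([0.5], [0.0], [1.0, 2.0], [0.68, 2.04])
        with pytest.raises(InsufficientStridesError):
            trj.spatiotemporal_params(left, right, events)
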