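"""Joint/pelvic angle extraction and per-cycle range of motion."""

import numpy as np
import pytest

from imugait import kinematics as kin
from imugait import quat
from imugait.calibration import SegmentAlignment
from imugait.errors import InsufficientCyclesError
from imugait.events import GaitCycle, validate_cycles
from imugait.frames import clinical_sign


def ident(placement="pelvis"):
    return SegmentAlignment.identity(placement)


def tile(q, n=5):
    return np.tile(q, (n, 1))


class TestJointAngles:
    def test_equal_orientations_give_zero(self):
        q = quat.quat_from_axis_angle(np.array([0.2, 0.7, 0.1]), 0.9)
        js = kin.joint_angle_series(tile(q), tile(q), ident(), ident(), "knee_r")
        assert np.abs(js.sagittal_deg).max() < 1e-9
        assert np.abs(js.frontal_deg).max() < 1e-9
        assert np.abs(js.transverse_deg).max() < 1e-9

    @pytest.mark.parametrize("joint", ["hip_l", "knee_r", "ankle_l"])
    def test_pure_mediolateral_rotation_maps_to_sagittal(self, joint):
        """30° of clinical joint motion about the mediolateral axis appears
        entirely in the sagittal plane with the joint's clinical sign."""
        sign = clinical_sign(joint)
        q_prox = tile(quat.quat_identity())
        q_dist = tile(quat.quat_from_axis_angle(np.array([1.0, 0, 0]), sign * np.radians(30)))
        js = kin.joint_angle_series(q_prox, q_dist, ident(), ident(), joint)
        assert js.sagittal_deg == pytest.approx(30.0, abs=1e-9)
        assert np.abs(js.frontal_deg).max() < 1e-9
        assert np.abs(js.transverse_deg).max() < 1e-9

    def test_truth_orientations_recover_truth_angles(self, default_truth):
        """Given exact segment orientations and identity alignments the
        kinematic chain reproduces the simulator's joint angles."""
        tr = default_truth
        for side in ("l", "r"):
            for joint, prox, dist in (
                (f"hip_{side}", "pelvis", f"thigh_{side}"),
                (f"knee_{side}", f"thigh_{side}", f"shank_{side}"),
                (f"ankle_{side}", f"shank_{side}", f"foot_{side}"),
            ):
                js = kin.joint_angle_series(
                    tr.orientations[prox],
                    tr.orientations[dist],
                    ident(prox),
                    ident(dist),
                    joint,
                    tr.time,
                )
                assert np.abs(js.sagittal_deg - tr.angles[joint]).max() < 1e-6

    def test_antisymmetry_under_prox_dist_swap(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            ang = rng.uniform(-30, 30)
            q_p = tile(quat.quat_identity(), 1)
            q_d = tile(quat.quat_from_axis_angle(np.array([1.0, 0, 0]), np.radians(ang)), 1)
            fwd = kin.joint_angle_series(q_p, q_d, ident(), ident(), "knee_r")
            rev = kin.joint_angle_series(q_d, q_p, ident(), ident(), "knee_r")
            assert fwd.sagittal_deg[0] == pytest.approx(-rev.sagittal_deg[0], abs=1e-9)

    def test_chain_consistency(self, default_truth):
        """Composing pelvis→thigh→shank→foot relative rotations reproduces
        the foot's global orientation."""
        tr = default_truth
        idx = slice(0, tr.time.size, 97)
        for side in ("l", "r"):
            q_p = tr.orientations["pelvis"][idx]
            q_t = tr.orientations[f"thigh_{side}"][idx]
            q_s = tr.orientations[f"shank_{side}"][idx]
            q_f = tr.orientations[f"foot_{side}"][idx]
            for qp, qt, qs, qf in zip(q_p, q_t, q_s, q_f):
                rel_hip = quat.quat_multiply(quat.quat_conjugate(qp), qt)
                rel_knee = quat.quat_multiply(quat.quat_conjugate(qt), qs)
                rel_ankle = quat.quat_multiply(quat.quat_conjugate(qs), qf)
                rebuilt = quat.quat_multiply(
                    quat.quat_multiply(quat.quat_multiply(qp, rel_hip), rel_knee), rel_ankle
                )
                assert quat.quat_angle_deg(rebuilt, qf) < 1e-9

    def test_euler_matches_matrix_oracle(self):
        rng = np.random.default_rng(1)
        qs = rng.standard_normal((200, 4))
        qs /= np.linalg.norm(qs, axis=1, keepdims=True)
        keep = np.abs(2 * (qs[:, 0] * qs[:, 2] - qs[:, 3] * qs[:, 1])) < 0.95
        yaw, pitch, roll = kin._euler_zyx_many(qs[keep])
        for q, y, p, r in zip(qs[keep], yaw, pitch, roll):
            m = quat.quat_to_matrix(q)
            assert r == pytest.approx(np.degrees(np.arctan2(m[2, 1], m[2, 2])), abs=1e-9)
            assert p == pytest.approx(np.degrees(-np.arcsin(m[2, 0])), abs=1e-9)
            assert y == pytest.approx(np.degrees(np.arctan2(m[1, 0], m[0, 0])), abs=1e-9)


class TestPelvicAngles:
    def test_neutral_standing_zero(self):
        ps = kin.pelvic_angle_series(tile(quat.quat_identity()), ident())
        assert np.abs(ps.tilt_deg).max() < 1e-9
        assert np.abs(ps.rotation_deg).max() < 1e-9

    def test_pure_vertical_rotation(self):
        q = quat.quat_from_axis_angle(np.array([0.0, 1.0, 0.0]), np.radians(10))
        ps = kin.pelvic_angle_series(tile(q), ident())
        assert ps.rotation_deg == pytest.approx(10.0, abs=1e-9)
        assert np.abs(ps.tilt_deg).max() < 1e-9

    def test_truth_recovery(self, default_truth):
        tr = default_truth
        ps = kin.pelvic_angle_series(tr.orientations["pelvis"], ident(), tr.time)
        assert np.abs(ps.tilt_deg - tr.angles["pelvic_tilt"]).max() < 1e-6
        assert np.abs(ps.rotation_deg - tr.angles["pelvic_rotation"]).max() < 1e-6


class TestCycleRom:
    def test_sinusoid_rom_is_twice_amplitude(self):
        fs, amp = 100.0, 17.0
        t = np.arange(0.0, 10.0, 1 / fs)
        series = amp * np.sin(2 * np.pi * 1.0 * t)
        cycles = [GaitCycle("r", float(k), float(k + 1), k + 0.6, 1.0, True) for k in range(9)]
        roms, mean = kin.cycle_rom(t, series, cycles)
        assert np.allclose(roms, 2 * amp, atol=0.05)
        assert mean == pytest.approx(np.mean(roms))

    def test_simulator_hip_rom_recovered(self, default_truth):
        """Trial-mean hip ROM over steady stable cycles matches the dense
        waveform range of the default profile (≈ 43°)."""
        tr = default_truth
        prof = tr.profile
        cycles = [
            c
            for c in validate_cycles(tr.events)
            if c.side == "r"
            and c.start >= prof.lead_in_s + 2 * prof.cycle_duration_s
            and c.end <= prof.lead_in_s + (prof.n_cycles - 0.5) * prof.cycle_duration_s
        ]
        _, mean_rom = kin.cycle_rom(tr.time, tr.angles["hip_r"], cycles, side="r")
        phi = np.linspace(0, 1, 2000)
        dense = prof.hip_mean_deg + sum(
            a * np.cos(2 * np.pi * k * phi + p)
            for k, (a, p) in enumerate(prof.hip_harmonics, start=1)
        )
        assert mean_rom == pytest.approx(dense.max() - dense.min(), abs=1.0)

    def test_no_stable_cycles_signals(self):
        with pytest.raises(InsufficientCyclesError):
            kin.cycle_rom(np.arange(10.0), np.zeros(10), [])
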