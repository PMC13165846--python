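"""End-to-end trial processing: calibration → filtering → events → parameters.

The batch driver emulates the on-line system in two passes: a first
orientation pass (no phase information) supports gait-event detection from
the foot nodes; the detected timeline then supplies the per-sample
stance/swing phase labels for the definitive second pass of the
phase-adaptive filter on all seven nodes, followed by ZUPT trajectory
reconstruction, spatiotemporal parameters, and joint/pelvic angles.
Everything is deterministic given the recording and configuration.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement as agr
from . import events as ev
from . import kinematics as kin
from . import trajectory as trj
from .calibration import SegmentAlignment, compute_neutral_alignment, estimate_gyro_bias
from .errors import ImuGaitError
from .frames import CHAIN, PLACEMENTS, side_of
from .io import PipelineConfig, TrialRecording
from .orientation import (
    PHASE_STANCE,
    PHASE_SWING,
    PHASE_UNINITIALIZED,
    estimate_orientation,
)
from .preprocess import preprocess_stream

__all__ = ["TrialReport", "run_pipeline", "phase_codes_from_events", "write_report"]


@dataclass
class TrialReport:
    time: np.ndarray
    status: dict
    gyro_bias: dict
    alignments: dict
    orientations: dict
    events: list
    thresholds: dict
    cycles: list
    foot_flat: dict
    trajectories: dict
    spatiotemporal: trj.SpatioTemporal | None
    joint_series: dict
    angles: dict  # sagittal/pelvic named series, degrees
    roms: dict
    agreement: dict | None
    alignment_lag_s: float | None
    config: PipelineConfig

    @property
    def ok(self) -> bool:
        return all(v.startswith("ok") for v in self.status.values())

    def config_hash(self) -> str:
        from .io import _params_to_dict

        d = _params_to_dict(self.config)
        d["ncf"] = _params_to_dict(self.config.ncf)
        return hashlib.sha256(yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:12]


def phase_codes_from_events(time: np.ndarray, side_events: list) -> np.ndarray:
    """Per-sample stance/swing codes from one foot's event timeline.

    Samples before the first detected event are ``uninitialized`` (the trial
    starts with a static stand, treated like stance by the filter); after
    that, HS opens a stance interval and TO opens a swing interval.
    """
    codes = np.full(time.size, PHASE_UNINITIALIZED, dtype=np.int8)
    evs = sorted(side_events, key=lambda e: e.time)
    for i, e in enumerate(evs):
        start = np.searchsorted(time, e.time)
        stop = np.searchsorted(time, evs[i + 1].time) if i + 1 < len(evs) else time.size
        codes[start:stop] = PHASE_STANCE if e.type == "HS" else PHASE_SWING
    return codes


def _pelvis_phase_codes(time: np.ndarray, foot_flat: dict, first_event_t: float) -> np.ndarray:
    """Pelvis uses the high integral gain whenever any foot is foot-flat."""
    codes = np.full(time.size, PHASE_SWING, dtype=np.int8)
    for intervals in foot_flat.values():
        for a, b in intervals:
            codes[np.searchsorted(time, a) : np.searchsorted(time, b)] = PHASE_STANCE
    codes[time < first_event_t] = PHASE_UNINITIALIZED
    return codes


def run_pipeline(
    recording: TrialRecording,
    config: PipelineConfig | None = None,
    reference: tuple | None = None,
) -> TrialReport:
    """Process one seven-node trial; optionally compare against a reference.

    ``reference`` is ``(time_ref, {variable: series_deg})`` at the reference
    system's own rate.  Stage failures are recorded in ``report.status`` and
    downstream stages that depend on them are skipped; independent stages
    still complete.
    """
    cfg = config or PipelineConfig()
    status: dict[str, str] = {}
    time = recording.node("pelvis").time
    fs = recording.fs
    n_static = int(round(cfg.static_window_s * fs))

    # --- calibration: gyro bias from the initial static stand
    gyro_bias: dict[str, np.ndarray] = {}
    filtered: dict[str, tuple] = {}
    try:
        for p in PLACEMENTS:
            s = recording.node(p)
            gyro_bias[p] = estimate_gyro_bias(s.gyro[:n_static], fs)
        status["calibration"] = "ok"
    except ImuGaitError as e:
        status["calibration"] = f"error: {e}"
        gyro_bias = {p: np.zeros(3) for p in PLACEMENTS}

    # --- cascaded preprocessing
    for p in PLACEMENTS:
        s = recording.node(p)
        filtered[p] = preprocess_stream(s.gyro - gyro_bias[p], s.accel, s.mag)
    status["preprocess"] = "ok"

    # --- pass 1 orientation (no phase labels) + neutral alignment
    orientations1: dict[str, np.ndarray] = {}
    alignments: dict[str, SegmentAlignment] = {}
    try:
        for p in PLACEMENTS:
            g, a, m = filtered[p]
            orientations1[p] = estimate_orientation(time, g, a, m, cfg.ncf)
            alignments[p] = compute_neutral_alignment(orientations1[p][:n_static], p, fs)
        status["orientation_pass1"] = "ok"
    except ImuGaitError as e:
        status["orientation_pass1"] = f"error: {e}"
        raise

    # --- gait events from the foot nodes.  A side where the thresholds never
    # initialize (e.g. a static capture with no steps) contributes no events;
    # that is an outcome, not a failure.
    events: list[ev.GaitEvent] = []
    thresholds: dict[str, ev.ThresholdSet] = {}
    notes = []
    for side in ("l", "r"):
        p = f"foot_{side}"
        g, a, m = filtered[p]
        a_vert = ev.vertical_acceleration(orientations1[p], a)
        w_sag = ev.sagittal_rate(g, alignments[p].quaternion)
        try:
            side_events, thr = ev.detect_events_adaptive(
                a_vert,
                w_sag,
                fs,
                side=side,
                time=time,
                coefficient=cfg.threshold_coefficient,
                n_init_cycles=cfg.n_init_cycles,
            )
            events.extend(side_events)
            thresholds[side] = thr
        except ImuGaitError as e:
            notes.append(f"{side}: {e}")
    events.sort(key=lambda e: e.time)
    status["events"] = "ok" if not notes else "ok (no events: " + "; ".join(notes) + ")"
    cycles = ev.validate_cycles(events)

    # --- foot-flat detection (sensor-frame norms, mounting independent)
    foot_flat: dict[str, list] = {}
    for side in ("l", "r"):
        p = f"foot_{side}"
        g, a, _ = filtered[p]
        side_events = [e for e in events if e.side == side]
        if side_events:
            intervals, n_missing = trj.detect_foot_flat(time, g, a, side_events, side=side)
        else:
            intervals, n_missing = [], 0
        foot_flat[side] = intervals
    status["foot_flat"] = "ok"

    # --- pass 2 orientation with phase labels
    side_codes = {
        s: phase_codes_from_events(time, [e for e in events if e.side == s]) for s in ("l", "r")
    }
    first_t = min((e.time for e in events), default=time[-1])
    orientations: dict[str, np.ndarray] = {}
    for p in PLACEMENTS:
        side = side_of(p)
        codes = side_codes[side] if side else _pelvis_phase_codes(time, foot_flat, first_t)
        g, a, m = filtered[p]
        orientations[p] = estimate_orientation(time, g, a, m, cfg.ncf, phase_codes=codes)
    status["orientation"] = "ok"

    # --- ZUPT trajectories and spatiotemporal parameters
    trajectories: dict[str, trj.FootTrajectory] = {}
    spatiotemporal = None
    try:
        for side in ("l", "r"):
            p = f"foot_{side}"
            _, a, _ = filtered[p]
            trajectories[side] = trj.reconstruct_trajectory(
                time, a, orientations[p], foot_flat[side], side=side
            )
        spatiotemporal = trj.spatiotemporal_params(
            trajectories["l"], trajectories["r"], events, stride_variant=cfg.stride_variant
        )
        status["spatiotemporal"] = "ok"
    except ImuGaitError as e:
        status["spatiotemporal"] = f"error: {e}"

    # --- joint and pelvic kinematics
    joint_series: dict[str, kin.JointAngleSeries] = {}
    angles: dict[str, np.ndarray] = {}
    for side in ("l", "r"):
        for joint, prox, dist in CHAIN[side]:
            js = kin.joint_angle_series(
                orientations[prox],
                orientations[dist],
                alignments[prox],
                alignments[dist],
                joint,
                time,
            )
            joint_series[joint] = js
            angles[joint] = js.sagittal_deg
    pelvic = kin.pelvic_angle_series(orientations["pelvis"], alignments["pelvis"], time)
    angles["pelvic_tilt"] = pelvic.tilt_deg
    angles["pelvic_rotation"] = pelvic.rotation_deg
    status["kinematics"] = "ok"

    # --- per-cycle range of motion
    roms: dict[str, tuple] = {}
    for name, series in angles.items():
        side = side_of(name)
        try:
            roms[name] = kin.cycle_rom(time, series, cycles, side=side)
        except ImuGaitError:
            pass

    # --- agreement against a reference, if supplied
    agreement_out = None
    lag_s = None
    if reference is not None:
        try:
            agreement_out, lag_s = _compare_with_reference(time, angles, reference, cfg)
            status["agreement"] = "ok"
        except ImuGaitError as e:
            status["agreement"] = f"error: {e}"

    return TrialReport(
        time=time,
        status=status,
        gyro_bias=gyro_bias,
        alignments=alignments,
        orientations=orientations,
        events=events,
        thresholds=thresholds,
        cycles=cycles,
        foot_flat=foot_flat,
        trajectories=trajectories,
        spatiotemporal=spatiotemporal,
        joint_series=joint_series,
        angles=angles,
        roms=roms,
        agreement=agreement_out,
        alignment_lag_s=lag_s,
        config=cfg,
    )


def _pelvic_motion_channel(time: np.ndarray, tilt: np.ndarray, rot: np.ndarray) -> np.ndarray:
    """Pelvic angular-rate magnitude — the alignment channel (avoids circular
    dependence on the limb joint angles under validation)."""
    dt = float(np.median(np.diff(time)))
    return np.hypot(np.gradient(tilt, dt), np.gradient(rot, dt))


def _compare_with_reference(
    time: np.ndarray, angles: dict, reference: tuple, cfg: PipelineConfig
) -> tuple[dict, float]:
    t_ref, ref_angles = reference
    t_ref = np.asarray(t_ref, dtype=float)
    fs_test = 1.0 / float(np.median(np.diff(time)))
    fs_ref = 1.0 / float(np.median(np.diff(t_ref)))

    ref_filt = {
        k: agr.zero_lag_butterworth(v, fs_ref, cfg.reference_cutoff_hz)
        for k, v in ref_angles.items()
    }
    # both alignment channels see the same zero-lag low-pass so the
    # correlation peak is not biased by asymmetric smoothing
    ch_test = _pelvic_motion_channel(
        time,
        agr.zero_lag_butterworth(angles["pelvic_tilt"], fs_test, cfg.reference_cutoff_hz),
        agr.zero_lag_butterworth(angles["pelvic_rotation"], fs_test, cfg.reference_cutoff_hz),
    )
    ch_ref = _pelvic_motion_channel(t_ref, ref_filt["pelvic_tilt"], ref_filt["pelvic_rotation"])
    pair = agr.align_by_xcorr(
        ch_test, fs_test, ch_ref, fs_ref, search_s=cfg.align_search_s, fs_out=cfg.output_fs
    )
    grid = pair.time
    out: dict[str, agr.AgreementReport] = {}
    for name, ref_series in ref_filt.items():
        key = name if name in angles else None
        if key is None:
            continue
        x = np.interp(grid, time + pair.lag_s, angles[key])
        y = np.interp(grid, t_ref, ref_series)
        out[name] = agr.agreement_metrics(x, y)
    return out, pair.lag_s


def write_report(report: TrialReport, outdir: str | Path, seed: int | None = None) -> None:
    """Write the trial report bundle: CSVs plus a markdown summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {"time_s": e.time, "type": e.type, "side": e.side, "sample": e.index}
            for e in report.events
        ]
    ).to_csv(outdir / "events.csv", index=False)

    rows = []
    for name, series in report.angles.items():
        rows.append(pd.DataFrame({"time_s": report.time, "variable": name, "angle_deg": series}))
    pd.concat(rows, ignore_index=True).to_csv(outdir / "angles.csv", index=False, float_format="%.6g")

    lines = [
        "# Trial report",
        "",
        f"- config hash: `{report.config_hash()}`",
        f"- seed: {seed if seed is not None else report.config.seed}",
        "",
        "## Stage status",
        "",
    ]
    lines += [f"- {k}: {v}" for k, v in report.status.items()]
    if report.spatiotemporal is not None:
        st = report.spatiotemporal
        pd.DataFrame(
            [
                {
                    "stride_length_m": st.stride_length_m,
                    "step_width_m": st.step_width_m,
                    "cadence_spm": st.cadence_spm,
                    "velocity_ms": st.velocity_ms,
                    "cycle_duration_s": st.cycle_duration_s,
                    "n_steps": st.n_steps,
                }
            ]
        ).to_csv(outdir / "spatiotemporal.csv", index=False)
        lines += [
            "",
            "## Spatiotemporal parameters",
            "",
            f"- stride length: {st.stride_length_m:.3f} m",
            f"- step width: {st.step_width_m:.3f} m",
            f"- cadence: {st.cadence_spm:.1f} steps/min",
            f"- walking velocity: {st.velocity_ms:.3f} m/s",
            f"- gait cycle: {st.cycle_duration_s:.3f} s",
        ]
    if report.roms:
        lines += ["", "## Mean range of motion (stable cycles)", ""]
        lines += [f"- {k}: {v[1]:.2f}°" for k, v in report.roms.items()]
    if report.agreement:
        lines += ["", "## Agreement vs reference", ""]
        pd.DataFrame(
            [
                {
                    "variable": k,
                    "rmse": r.rmse,
                    "relative_rmse_pct": r.relative_rmse_pct,
                    "pearson_r": r.pearson_r,
                    "bias": r.bias,
                    "loa_low": r.loa_low,
                    "loa_high": r.loa_high,
                    "icc": r.icc,
                    "n": r.n,
                }
                for k, r in report.agreement.items()
            ]
        ).to_csv(outdir / "agreement.csv", index=False)
        lines += [
            f"- {k}: RMSE {r.rmse:.2f}, r {r.pearson_r:.3f}, ICC {r.icc:.3f}"
            for k, r in report.agreement.items()
        ]
    (outdir / "summary.md").write_text("\n".join(lines) + "\n")
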