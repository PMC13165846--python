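"""Shared measurement helpers for the test suite."""

import numpy as np

from imugait import quat
from imugait.kinematics import segment_orientations


def event_f1(detected, truth_events, tol_s=0.05):
    """(F1, precision, recall) matching events by type, side, and time."""
    used = set()
    tp = 0
    for e in detected:
        cands = [
            (abs(e.time - te.time), i)
            for i, te in enumerate(truth_events)
            if te.type == e.type and te.side == e.side and i not in used
        ]
        if cands and min(cands)[0] <= tol_s:
            tp += 1
            used.add(min(cands)[1])
    precision = tp / len(detected) if detected else 0.0
    recall = tp / len(truth_events) if truth_events else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return f1, precision, recall


def max_timing_error_s(detected, truth_events):
    errs = []
    for e in detected:
        cands = [
            abs(e.time - te.time)
            for te in truth_events
            if te.type == e.type and te.side == e.side
        ]
        if cands:
            errs.append(min(cands))
    return max(errs) if errs else float("inf")


def orientation_rmse_deg(report, truth, placement, step=5):
    """RMSE of the aligned segment orientation against the simulator truth."""
    qs = segment_orientations(report.orientations[placement], report.alignments[placement])
    errs = [
        quat.quat_angle_deg(a, b)
        for a, b in zip(qs[::step], truth.orientations[placement][::step])
    ]
    return float(np.sqrt(np.mean(np.square(errs))))


def angle_rmse_deg(report, truth, name):
    d = report.angles[name] - truth.angles[name]
    return float(np.sqrt(np.mean(d**2)))


def stride_errors_pct(report, truth, side):
    true_strides = np.diff(truth.contact_positions[side][:, 2])
    est = np.asarray(report.spatiotemporal.stride_lengths[side])
    k = min(len(est), len(true_strides))
    return 100.0 * np.abs(est[:k] - true_strides[:k]) / true_strides[:k]
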