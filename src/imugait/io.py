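"""File formats and configuration for the seven-node trial pipeline.

A trial is a single long-format CSV, one row per node per sample:

    time_s,node,gx,gy,gz,ax,ay,az,mx,my,mz

with gyroscope in rad/s, accelerometer in m/s², magnetometer in arbitrary
(roughly unit) field units.  Angles and all human-facing outputs are in
degrees; files stay SI throughout to prevent silent unit bugs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidArgumentError, MissingNodeError
from .frames import PLACEMENTS
from .orientation import NcfParams
from .preprocess import CascadeConfig

log = logging.getLogger("imugait")

__all__ = [
    "NodeStream",
    "TrialRecording",
    "PipelineConfig",
    "read_trial_csv",
    "write_trial_csv",
    "load_config",
    "save_config",
    "write_calibration_file",
    "read_calibration_file",
]

CSV_COLUMNS = ["time_s", "node", "gx", "gy", "gz", "ax", "ay", "az", "mx", "my", "mz"]


@dataclass
class NodeStream:
    """One IMU node's timestamped samples with its anatomical placement."""

    placement: str
    time: np.ndarray  # (n,) seconds
    gyro: np.ndarray  # (n, 3) rad/s
    accel: np.ndarray  # (n, 3) m/s² (specific force)
    mag: np.ndarray  # (n, 3) arbitrary units

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    def __len__(self) -> int:
        return int(self.time.size)


@dataclass
class TrialRecording:
    """Seven placement-keyed node streams sharing a common time base."""

    streams: dict
    subject_id: str = "anonymous"
    trial_id: str = "trial"
    fs: float = 200.0
    #: end of the initial static standing segment, seconds
    static_end_s: float = 2.0

    def node(self, placement: str) -> NodeStream:
        try:
            return self.streams[placement]
        except KeyError:
            raise MissingNodeError(f"recording has no node for placement {placement!r}")


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, with validated defaults."""

    ncf: NcfParams = field(default_factory=NcfParams)
    threshold_coefficient: float = 0.6
    n_init_cycles: int = 3
    static_window_s: float = 2.0
    stride_variant: str = "projection"
    align_search_s: float = 2.0
    reference_cutoff_hz: float = 6.0
    output_fs: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.threshold_coefficient <= 1):
            raise InvalidArgumentError("threshold coefficient must be in (0, 1]")
        if self.static_window_s <= 0:
            raise InvalidArgumentError("static window must be positive")


def write_trial_csv(recording: TrialRecording, path: str | Path) -> None:
    frames = []
    for placement, s in recording.streams.items():
        df = pd.DataFrame(
            {
                "time_s": s.time,
                "node": placement,
                "gx": s.gyro[:, 0],
                "gy": s.gyro[:, 1],
                "gz": s.gyro[:, 2],
                "ax": s.accel[:, 0],
                "ay": s.accel[:, 1],
                "az": s.accel[:, 2],
                "mx": s.mag[:, 0],
                "my": s.mag[:, 1],
                "mz": s.mag[:, 2],
            }
        )
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["time_s", "node"], kind="stable")
    out.to_csv(path, index=False, float_format="%.9g")


def read_trial_csv(
    path: str | Path,
    *,
    require_all_nodes: bool = True,
    fs: float = 200.0,
    static_end_s: float = 2.0,
) -> TrialRecording:
    """Parse and validate a trial CSV.

    Out-of-order timestamps within a node are rejected; gaps longer than
    three sample periods are logged as dropped-sample warnings.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise InvalidArgumentError(f"cannot parse {path}: {exc}") from exc
    missing_cols = set(CSV_COLUMNS) - set(df.columns)
    if missing_cols:
        raise InvalidArgumentError(f"{path}: missing columns {sorted(missing_cols)}")
    if df[CSV_COLUMNS[2:]].isna().any().any() or df["time_s"].isna().any():
        bad = int(df[df.isna().any(axis=1)].index[0]) + 2  # header + 1-based
        raise InvalidArgumentError(f"{path}: malformed row near line {bad}")

    streams: dict[str, NodeStream] = {}
    for placement, g in df.groupby("node", sort=False):
        t = g["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0])
            raise InvalidArgumentError(
                f"{path}: non-monotone timestamps for node {placement!r} near sample {bad}"
            )
        gaps = np.flatnonzero(np.diff(t) > 3.0 / fs)
        if gaps.size:
            log.warning("node %s: %d gaps longer than 3 sample periods", placement, gaps.size)
        streams[str(placement)] = NodeStream(
            str(placement),
            t,
            g[["gx", "gy", "gz"]].to_numpy(dtype=float),
            g[["ax", "ay", "az"]].to_numpy(dtype=float),
            g[["mx", "my", "mz"]].to_numpy(dtype=float),
        )
    if require_all_nodes:
        absent = [p for p in PLACEMENTS if p not in streams]
        if absent:
            raise MissingNodeError(f"{path}: missing node(s) {absent}")
    return TrialRecording(streams, fs=fs, static_end_s=static_end_s)


def _params_to_dict(obj) -> dict:
    d = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        d[f.name] = v.tolist() if isinstance(v, np.ndarray) else v
    return d


def save_config(config: PipelineConfig, path: str | Path) -> None:
    d = _params_to_dict(config)
    d["ncf"] = _params_to_dict(config.ncf)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_config(path: str | Path) -> PipelineConfig:
    d = yaml.safe_load(Path(path).read_text()) or {}
    ncf = NcfParams(**d.pop("ncf", {})) if "ncf" in d else NcfParams()
    return PipelineConfig(ncf=ncf, **d)


def write_calibration_file(calibrations: dict, path: str | Path) -> None:
    """Serialize per-node calibration results as a human-readable YAML file.

    ``calibrations`` maps placement -> dict with any of ``gyro_bias`` (3,),
    ``accel`` (AccelCalibration), ``mag`` (MagCalibration),
    ``alignment`` (SegmentAlignment).
    """
    out: dict = {}
    for placement, cal in calibrations.items():
        block: dict = {}
        if "gyro_bias" in cal:
            block["gyro_bias_rad_s"] = np.asarray(cal["gyro_bias"]).tolist()
        if "accel" in cal:
            block["accel_scale"] = cal["accel"].scale.tolist()
            block["accel_bias_ms2"] = cal["accel"].bias.tolist()
        if "mag" in cal:
            block["mag_offset"] = cal["mag"].offset.tolist()
            block["mag_soft_iron"] = cal["mag"].soft_iron.tolist()
        if "alignment" in cal:
            block["alignment_quaternion_wxyz"] = cal["alignment"].quaternion.tolist()
        out[placement] = block
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))


def read_calibration_file(path: str | Path) -> dict:
    from .calibration import AccelCalibration, MagCalibration, SegmentAlignment

    raw = yaml.safe_load(Path(path).read_text()) or {}
    out: dict = {}
    for placement, block in raw.items():
        cal: dict = {}
        if "gyro_bias_rad_s" in block:
            cal["gyro_bias"] = np.array(block["gyro_bias_rad_s"])
        if "accel_scale" in block:
            cal["accel"] = AccelCalibration(
                np.array(block["accel_scale"]), np.array(block["accel_bias_ms2"])
            )
        if "mag_offset" in block:
            cal["mag"] = MagCalibration(
                np.array(block["mag_offset"]), np.array(block["mag_soft_iron"])
            )
        if "alignment_quaternion_wxyz" in block:
            cal["alignment"] = SegmentAlignment(
                np.array(block["alignment_quaternion_wxyz"]), placement
            )
        out[placement] = cal
    return out
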