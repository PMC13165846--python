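"""Three-stage cascaded per-channel preprocessing: clip → median → mean.

This mirrors the on-board conditioning chain of the sensor nodes: a clipping
stage bounds samples to the sensor full-scale range, a sliding median removes
single-sample outliers, and a short sliding mean smooths residual
fluctuation.  Windows are short (25 ms at 200 Hz by default) so heel-strike
impulses, which span several samples, survive.

Boundary handling uses shrinking windows (``min_periods=1``), so no padded
samples are fabricated at the edges of a trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidArgumentError
from .frames import GRAVITY

__all__ = ["CascadeConfig", "cascade_filter", "preprocess_stream"]


@dataclass
class CascadeConfig:
    """Configuration of the cascaded filter for one channel family.

    Clip limits default to the sensor full-scale ranges (±8 g accelerometer,
    ±1000 °/s gyroscope) in SI units.
    """

    clip_low: float
    clip_high: float
    median_window: int = 5
    mean_window: int = 5

    def __post_init__(self) -> None:
        if self.clip_low >= self.clip_high:
            raise InvalidArgumentError("clip_low must be below clip_high")
        for w in (self.median_window, self.mean_window):
            if w < 1 or w % 2 == 0:
                raise InvalidArgumentError(f"window lengths must be odd and >= 1, got {w}")

    @classmethod
    def accel_default(cls) -> "CascadeConfig":
        fs_limit = 8.0 * GRAVITY
        return cls(-fs_limit, fs_limit)

    @classmethod
    def gyro_default(cls) -> "CascadeConfig":
        fs_limit = math.radians(1000.0)
        return cls(-fs_limit, fs_limit)

    @classmethod
    def mag_default(cls) -> "CascadeConfig":
        # magnetometer values are in arbitrary units; clip generously
        return cls(-100.0, 100.0)


def cascade_filter(series: np.ndarray, cfg: CascadeConfig) -> np.ndarray:
    """Apply clip → sliding median → sliding mean to one channel."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise InvalidArgumentError("cascade_filter expects a 1-D series")
    max_window = max(cfg.median_window, cfg.mean_window)
    if series.size < max_window:
        raise InsufficientDataError(
            f"series length {series.size} shorter than window {max_window}"
        )
    clipped = np.clip(series, cfg.clip_low, cfg.clip_high)
    s = pd.Series(clipped)
    med = s.rolling(cfg.median_window, center=True, min_periods=1).median()
    out = med.rolling(cfg.mean_window, center=True, min_periods=1).mean()
    return out.to_numpy()


def preprocess_stream(
    gyro: np.ndarray,
    accel: np.ndarray,
    mag: np.ndarray,
    gyro_cfg: CascadeConfig | None = None,
    accel_cfg: CascadeConfig | None = None,
    mag_cfg: CascadeConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cascade-filter every channel of one node's (n, 3) gyro/accel/mag arrays."""
    gyro_cfg = gyro_cfg or CascadeConfig.gyro_default()
    accel_cfg = accel_cfg or CascadeConfig.accel_default()
    mag_cfg = mag_cfg or CascadeConfig.mag_default()

    def per_axis(arr: np.ndarray, cfg: CascadeConfig) -> np.ndarray:
        arr = np.asarray(arr, dtype=float)
        return np.column_stack([cascade_filter(arr[:, i], cfg) for i in range(arr.shape[1])])

    return per_axis(gyro, gyro_cfg), per_axis(accel, accel_cfg), per_axis(mag, mag_cfg)
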