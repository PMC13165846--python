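"""Reference comparison: filtering, alignment, resampling, agreement statistics.

This is the method-comparison half of the toolkit: a reference angle series
(e.g. from optical motion capture) is low-pass filtered with a zero-lag
fourth-order Butterworth at 6 Hz, temporally aligned to the wearable
estimate by normalized cross-correlation of a pelvic motion channel, both
are linearly resampled to a common 100 Hz base, and standard agreement
statistics are computed: RMSE, relative RMSE (percent of the reference
mean), Pearson r, mean bias, 95% Bland–Altman limits of agreement
(bias ± 1.96 × sample SD of the differences), and ICC(2,1) — two-way random
effects, absolute agreement, single measurement, the conventional choice for
method comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt
from scipy.stats import pearsonr

from .errors import AlignmentFailureError, InsufficientDataError, InvalidArgumentError

__all__ = [
    "AlignedPair",
    "AgreementReport",
    "zero_lag_butterworth",
    "align_by_xcorr",
    "agreement_metrics",
    "relative_rmse",
    "icc_2_1",
]


@dataclass
class AlignedPair:
    time: np.ndarray  # common 100 Hz base
    test: np.ndarray
    reference: np.ndarray
    lag_s: float  # positive: the test stream leads the reference by lag_s
    peak_correlation: float


@dataclass
class AgreementReport:
    rmse: float
    relative_rmse_pct: float
    pearson_r: float
    bias: float
    loa_low: float
    loa_high: float
    icc: float
    n: int
    undefined_reason: str | None = None


def zero_lag_butterworth(
    series: np.ndarray, fs: float, fc: float = 6.0, order: int = 4
) -> np.ndarray:
    """Forward–backward order-4 Butterworth low-pass (zero net phase, DC gain 1)."""
    s = np.asarray(series, dtype=float)
    if fs <= 2 * fc:
        raise InvalidArgumentError(f"fs={fs} must exceed 2·fc={2 * fc}")
    b, a = butter(order, fc, fs=fs)
    padlen = 3 * max(len(a), len(b))
    if s.size <= padlen:
        raise InsufficientDataError(f"series length {s.size} too short for zero-lag filtering")
    return filtfilt(b, a, s)


def _resample(time: np.ndarray, series: np.ndarray, new_time: np.ndarray) -> np.ndarray:
    return np.interp(new_time, time, series)


def align_by_xcorr(
    test: np.ndarray,
    fs_test: float,
    reference: np.ndarray,
    fs_ref: float,
    *,
    search_s: float = 2.0,
    fs_out: float = 100.0,
    min_peak: float = 0.5,
) -> AlignedPair:
    """Lag estimation by normalized cross-correlation on a common 100 Hz base.

    Both series are linearly resampled to ``fs_out``; the integer-sample lag
    within ±``search_s`` maximizing the normalized correlation is selected.
    A positive ``lag_s`` means the test stream leads the reference; the test
    series is delayed by ``lag_s`` before resampling so the returned pair is
    point-by-point comparable.  A correlation peak below ``min_peak`` raises
    :class:`AlignmentFailureError`.
    """
    t_test = np.arange(len(test)) / fs_test
    t_ref = np.arange(len(reference)) / fs_ref
    overlap = min(t_test[-1], t_ref[-1])
    if overlap < 2.0:
        raise InsufficientDataError("need at least 2 s of overlap for alignment")
    grid = np.arange(0.0, overlap, 1.0 / fs_out)
    x = _resample(t_test, np.asarray(test, dtype=float), grid)
    y = _resample(t_ref, np.asarray(reference, dtype=float), grid)

    max_lag = int(round(search_s * fs_out))
    best_lag, best_r = 0, -np.inf
    n = grid.size
    # smallest |lag| first, so exact ties (periodic or featureless channels)
    # resolve to the smallest shift
    for lag in sorted(range(-max_lag, max_lag + 1), key=abs):
        if lag >= 0:
            a, b = x[lag:], y[: n - lag]
        else:
            a, b = x[: n + lag], y[-lag:]
        if a.size < max(8, n - max_lag):
            continue
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            continue
        r = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
        if r > best_r + 1e-12:
            best_r, best_lag = r, lag
    if best_r < min_peak:
        raise AlignmentFailureError(
            f"cross-correlation peak {best_r:.2f} below {min_peak}; alignment not trusted"
        )
    # x[best_lag + i] ≈ y[i], i.e. the test stream lags the reference by
    # -best_lag samples; shifting it by lag_s aligns the pair
    lag_s = -best_lag / fs_out
    x_aligned = _resample(t_test + lag_s, np.asarray(test, dtype=float), grid)
    return AlignedPair(grid, x_aligned, y, lag_s, best_r)


def relative_rmse(rmse: float, reference_mean: float) -> float:
    """Relative RMSE in percent: ``100 · RMSE / reference mean``."""
    if reference_mean == 0:
        raise InvalidArgumentError("reference mean is zero; relative RMSE undefined")
    return 100.0 * rmse / reference_mean


def icc_2_1(test: np.ndarray, reference: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measurement.

    McGraw–Wong "ICC(A,1)" — the conventional index for method comparison.
    """
    import warnings

    import pandas as pd
    import pingouin as pg

    n = len(test)
    data = pd.DataFrame(
        {
            "target": np.tile(np.arange(n), 2),
            "rater": np.repeat(["test", "reference"], n),
            "rating": np.concatenate([test, reference]),
        }
    )
    with warnings.catch_warnings():
        # degenerate (zero-residual) inputs produce harmless inf/nan F stats
        warnings.simplefilter("ignore", RuntimeWarning)
        table = pg.intraclass_corr(
            data=data, targets="target", raters="rater", ratings="rating"
        )
    row = table[table["Type"].isin(["ICC(A,1)", "ICC2"])]
    return float(row["ICC"].iloc[0])


def agreement_metrics(test: np.ndarray, reference: np.ndarray) -> AgreementReport:
    """Full agreement panel for one variable's paired observations."""
    x = np.asarray(test, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("paired observations must be equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"need >= 3 pairs, got {n}")
    diff = x - y
    rmse = float(np.sqrt(np.mean(diff**2)))
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))  # sample SD, the Bland–Altman convention
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    rel = relative_rmse(rmse, float(y.mean())) if y.mean() != 0 else math.nan

    undefined = None
    if x.std() == 0 or y.std() == 0:
        if np.array_equal(x, y):
            r, icc = 1.0, 1.0  # identical constant series agree perfectly
        else:
            r, icc = math.nan, math.nan
            undefined = "zero-variance input: correlation and ICC undefined"
    else:
        r = float(pearsonr(x, y).statistic)
        icc = icc_2_1(x, y)
    return AgreementReport(rmse, rel, r, bias, loa_low, loa_high, icc, n, undefined)
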