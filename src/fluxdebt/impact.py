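"""Relative non-stationarity (RN) impact detection on per-period series.

For each trailing window of ``window_len`` periods (default 45, about three
years of 24-day periods) the series is regressed on time; the fitted change
over the window, dx = slope x span, is normalized by the window mean:

    RN = dx / mean(window)

A seasonal harmonic pair (cos/sin at the annual period) is included in the
regression so the annual cycle does not masquerade as a trend.  Impact
thresholds are empirical percentiles of |RN| over the entire record, and
the impact duration after a disturbance is the time from landfall to the
end of the first exceedance run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_WINDOW = 45
DEFAULT_PERCENTILES = (85.0, 90.0, 95.0)


def _window_rn(values: np.ndarray, t: np.ndarray, seasonal_period: float) -> float:
    mean = values.mean()
    if mean == 0.0:
        return np.nan
    tc = t - t[0]
    w = 2 * np.pi / seasonal_period
    X = np.column_stack([np.ones_like(tc), tc, np.cos(w * tc), np.sin(w * tc)])
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    dx = beta[1] * (t[-1] - t[0])
    return float(dx / mean)


def rn_statistic(values, times=None, window_len: int = DEFAULT_WINDOW,
                 seasonal_period: float | None = None) -> np.ndarray:
    """RN per trailing window, aligned to the window-end period.

    ``times`` defaults to the sample index; then the seasonal period
    defaults to ``window_len / 3`` samples (one year of a three-year
    window).  With explicit times (e.g. period end dates in days) pass the
    annual period explicitly (365).  Windows containing any missing value
    are skipped (NaN), as is any window whose mean is zero.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if window_len < 3:
        raise ValueError("window_len must be >= 3")
    if n < window_len:
        raise ValueError(f"series length {n} < window_len {window_len}")
    if times is None:
        times = np.arange(n, dtype=float)
        if seasonal_period is None:
            seasonal_period = window_len / 3.0
    else:
        times = np.asarray(times, dtype=float)
        if seasonal_period is None:
            raise ValueError("seasonal_period is required with explicit times")
    rn = np.full(n, np.nan)
    for end in range(window_len - 1, n):
        w = values[end - window_len + 1:end + 1]
        if not np.all(np.isfinite(w)):
            continue
        rn[end] = _window_rn(w, times[end - window_len + 1:end + 1], seasonal_period)
    return rn


def impact_thresholds(rn, percentiles=DEFAULT_PERCENTILES) -> dict[float, float]:
    """Percentile thresholds of |RN| over the full record (linear interp)."""
    percentiles = list(percentiles)
    if any(not (0.0 < p < 100.0) for p in percentiles):
        raise ValueError("percentiles must lie strictly in (0, 100)")
    rn = np.asarray(rn, dtype=float)
    mag = np.abs(rn[np.isfinite(rn)])
    if len(mag) < 10:
        raise ValueError(f"need >= 10 defined RN values, got {len(mag)}")
    vals = np.percentile(mag, percentiles)
    return dict(zip(percentiles, (float(v) for v in vals)))


def impact_duration(rn, period_ends, landfall_date, threshold: float) -> float:
    """Days from landfall to the last post-landfall |RN| exceedance.

    The impact lasts until the final period whose |RN| is still above the
    threshold, interruptions included, so durations are monotone
    non-increasing in the threshold.  Returns 0 if no post-landfall period
    exceeds it.
    """
    rn = np.asarray(rn, dtype=float)
    ends = pd.DatetimeIndex(period_ends)
    landfall = pd.Timestamp(landfall_date)
    post = np.flatnonzero(ends > landfall)
    if len(post) == 0:
        return 0.0
    exceed = post[np.isfinite(rn[post]) & (np.abs(rn[post]) > threshold)]
    if len(exceed) == 0:
        return 0.0
    return float((ends[exceed[-1]] - landfall).days)


@dataclass
class ImpactSeries:
    """RN trace, thresholds and impact durations for one variable."""
    variable: str
    rn: np.ndarray
    period_ends: pd.DatetimeIndex
    window_len: int = DEFAULT_WINDOW
    thresholds: dict[float, float] = field(default_factory=dict)
    durations: dict[float, float] = field(default_factory=dict)


def analyze_impact(values, period_ends, landfall_date, variable: str = "",
                   window_len: int = DEFAULT_WINDOW,
                   seasonal_period: float = 365.0,
                   percentiles=DEFAULT_PERCENTILES) -> ImpactSeries:
    """RN, full-record percentile thresholds and post-landfall durations."""
    ends = pd.DatetimeIndex(period_ends)
    t_days = ends.asi8 / (86400 * 1e9)
    rn = rn_statistic(values, times=t_days, window_len=window_len,
                      seasonal_period=seasonal_period)
    thresholds = impact_thresholds(rn, percentiles)
    durations = {p: impact_duration(rn, ends, landfall_date, thr)
                 for p, thr in thresholds.items()}
    return ImpactSeries(variable=variable, rn=rn, period_ends=ends,
                        window_len=window_len, thresholds=thresholds,
                        durations=durations)
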