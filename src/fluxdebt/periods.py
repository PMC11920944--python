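"""24-day period calendar and a no-leap half-hourly time grid.

Carbon-exchange parameters are estimated in 24-day windows tiling each
calendar year: period 1 starts January 1, periods 1-14 are 24 days, and
period 15 absorbs the year remainder (29 days, 30 when a leap day is
present in the input calendar).  Simulated series use a fixed 365-day year
(leap days dropped), so one simulated year is always 365 x 48 half-hours.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np
import pandas as pd

PERIOD_DAYS = 24
PERIODS_PER_YEAR = 15
HALFHOURS_PER_DAY = 48
DAYS_PER_YEAR = 365


def build_periods(years: Iterable[int] | int) -> pd.DataFrame:
    """Build the 24-day period calendar for one or more calendar years.

    Returns a DataFrame with columns ``year``, ``period`` (1..15),
    ``start`` (inclusive) and ``end`` (exclusive).  Periods tile each year
    exactly: period 1 starts Jan 1 and period 15 runs to Jan 1 of the next
    year.
    """
    if np.isscalar(years):
        years = [int(years)]
    years = sorted(int(y) for y in years)
    if not years:
        raise ValueError("at least one year is required")
    rows = []
    for year in years:
        jan1 = pd.Timestamp(year=year, month=1, day=1)
        next_jan1 = pd.Timestamp(year=year + 1, month=1, day=1)
        for p in range(1, PERIODS_PER_YEAR + 1):
            start = jan1 + pd.Timedelta(days=(p - 1) * PERIOD_DAYS)
            if p < PERIODS_PER_YEAR:
                end = start + pd.Timedelta(days=PERIOD_DAYS)
            else:
                end = next_jan1
            rows.append({"year": year, "period": p, "start": start, "end": end})
    return pd.DataFrame(rows)


def assign_periods(timestamps: pd.DatetimeIndex | pd.Series,
                   calendar: pd.DataFrame) -> np.ndarray:
    """Map each timestamp to the row index of its period in ``calendar``.

    Timestamps outside the calendar span get -1.
    """
    ts = pd.DatetimeIndex(timestamps).asi8
    starts = pd.DatetimeIndex(calendar["start"]).asi8
    ends = pd.DatetimeIndex(calendar["end"]).asi8
    idx = np.searchsorted(starts, ts, side="right") - 1
    idx = idx.astype(np.int64)
    bad = (idx < 0) | (ts >= ends[np.clip(idx, 0, len(ends) - 1)])
    idx[bad] = -1
    return idx


def noleap_halfhour_grid(start_date: str | pd.Timestamp, n_years: int) -> pd.DatetimeIndex:
    """Half-hourly timestamp grid spanning ``n_years`` 365-day years.

    Built on real calendar dates with every Feb 29 removed, so the length is
    exactly ``n_years * 365 * 48`` for whole-year spans.
    """
    if n_years < 1:
        raise ValueError(f"n_years must be >= 1, got {n_years}")
    start = pd.Timestamp(start_date)
    end = start + pd.DateOffset(years=int(n_years))
    grid = pd.date_range(start, end, freq="30min", inclusive="left")
    grid = grid[~((grid.month == 2) & (grid.day == 29))]
    return grid


def noleap_dayofyear(timestamps: pd.DatetimeIndex) -> np.ndarray:
    """Day of year on the 365-day calendar (Mar 1 is day 60 in every year)."""
    doy = timestamps.dayofyear.to_numpy().astype(float)
    leap = timestamps.is_leap_year
    doy = doy - (leap & (doy > 59))
    return doy


def noleap_day_number(timestamps) -> np.ndarray:
    """Integer day count on the 365-day calendar (year * 365 + doy - 1).

    Intervals measured on this scale span exactly 365 days per year even
    when the underlying real dates cross a (dropped) Feb 29; a stray
    Feb 29 record folds onto Feb 28.
    """
    ts = pd.DatetimeIndex(timestamps)
    return ts.year.to_numpy() * DAYS_PER_YEAR + (noleap_dayofyear(ts) - 1).astype(int)
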