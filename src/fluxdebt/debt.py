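"""Recovery-debt accounting in carbon units.

The recovery debt of NEE is the cumulative difference between
post-disturbance NEE and the mean pre-disturbance condition,

    debt = sum over half-hours of (NEE_post - mean NEE_pre),

converted from µmol CO2 m-2 s-1 to g C m-2.  Positive values are carbon
debt (a weakened sink); negative values are enhanced capture.  Annual
debts use landfall-anniversary 365-day years; "recovery of all lost
carbon" is the first year in which the cumulative debt drops to or below
zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .periods import DAYS_PER_YEAR, HALFHOURS_PER_DAY, noleap_day_number

SECONDS_PER_HALFHOUR = 1800.0
G_C_PER_UMOL_CO2 = 12.011e-6
SECONDS_PER_YEAR = DAYS_PER_YEAR * 86400.0
G_PER_TONNE = 1e6
TONNE_PER_MT = 1e6


def umol_per_s_to_gc_per_year(flux: float) -> float:
    """Convert a mean flux (µmol CO2 m-2 s-1) to g C m-2 over a 365-d year."""
    return flux * SECONDS_PER_YEAR * G_C_PER_UMOL_CO2


def gc_per_year_to_umol_per_s(total: float) -> float:
    """Inverse of :func:`umol_per_s_to_gc_per_year`."""
    return total / (SECONDS_PER_YEAR * G_C_PER_UMOL_CO2)


def _year_window(series: pd.DataFrame, landfall_date, year_offset: int):
    """NEE over one 365-day anniversary year on the no-leap day scale.

    ``year_offset`` 0 is the reference year ending at landfall; k >= 1 is
    the k-th post-landfall year.
    """
    day = noleap_day_number(series["timestamp"])
    d0 = noleap_day_number([pd.Timestamp(landfall_date)])[0]
    lo = d0 + (year_offset - 1) * DAYS_PER_YEAR
    sel = (day >= lo) & (day < lo + DAYS_PER_YEAR)
    return series.loc[sel, "nee"].to_numpy(dtype=float)


def reference_nee(series: pd.DataFrame, landfall_date,
                  min_frac: float = 0.8) -> float:
    """Mean NEE over the year before landfall, [landfall - 365 d, landfall).

    Raises if the window starts before the series or holds fewer than
    ``min_frac`` of its expected half-hours.
    """
    landfall = pd.Timestamp(landfall_date)
    first = pd.Timestamp(series["timestamp"].iloc[0])
    d0 = noleap_day_number([landfall])[0]
    if d0 - DAYS_PER_YEAR < noleap_day_number([first])[0]:
        raise ValueError("pre-landfall reference window extends before the "
                         "series start")
    nee = _year_window(series, landfall, 0)
    expected = DAYS_PER_YEAR * HALFHOURS_PER_DAY
    present = int(np.sum(np.isfinite(nee)))
    if present < min_frac * expected:
        raise ValueError(
            f"reference window only {present / expected:.0%} complete "
            f"(need >= {min_frac:.0%})")
    return float(np.nanmean(nee))


def annual_debt(reference: float, post_series: pd.DataFrame, landfall_date,
                year_k: int, fill_series: pd.DataFrame | None = None) -> float:
    """Recovery debt (g C m-2) for post-landfall year ``year_k`` (1-based).

    Gaps in the post series are filled from ``fill_series`` (typically a
    modeled-NEE variant); remaining gaps raise.
    """
    if year_k < 1:
        raise ValueError("year_k must be >= 1")
    nee = _year_window(post_series, landfall_date, year_k)
    if len(nee) == 0:
        raise ValueError(f"post series does not cover year {year_k}")
    if not np.all(np.isfinite(nee)):
        if fill_series is None:
            raise ValueError(
                f"gaps in post series for year {year_k} and no fill series "
                "supplied")
        fill = _year_window(fill_series, landfall_date, year_k)
        if len(fill) != len(nee) or not np.all(np.isfinite(fill[~np.isfinite(nee)])):
            raise ValueError("fill series does not cover the gaps")
        nee = np.where(np.isfinite(nee), nee, fill)
    return float(np.sum(nee - reference) * SECONDS_PER_HALFHOUR
                 * G_C_PER_UMOL_CO2)


def cumulative_debt(annual: list[float] | np.ndarray):
    """Running sum of annual debts and the year of full carbon recovery.

    Returns (cumulative array, recovery_year) where recovery_year is the
    first 1-based year with cumulative debt <= 0, or None.
    """
    annual = np.asarray(annual, dtype=float)
    cum = np.cumsum(annual)
    below = np.flatnonzero(cum <= 0)
    recovery_year = int(below[0]) + 1 if len(below) else None
    return cum, recovery_year


@dataclass
class LandscapeDebt:
    total_mt: float                # landscape total, Mt C
    per_pixel_t: np.ndarray        # tonnes C per pixel
    frac_negative: float           # fraction of pixels with debt < 0


def landscape_debt(pixel_debts, areas) -> LandscapeDebt:
    """Aggregate per-pixel debts (g C m-2) over pixel areas (m2) to Mt C.

    Also reports the fraction of pixels with negative debt (enhanced
    capture); pass year-4 cumulative debts to mirror the landscape
    recovery bookkeeping.
    """
    debts = np.asarray(pixel_debts, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if debts.shape != areas.shape:
        raise ValueError("pixel debts and areas must align")
    if not np.all(np.isfinite(areas)):
        raise ValueError("missing pixel area")
    tonnes = debts * areas / G_PER_TONNE
    return LandscapeDebt(total_mt=float(tonnes.sum() / TONNE_PER_MT),
                         per_pixel_t=tonnes,
                         frac_negative=float(np.mean(debts < 0)))


def summarize_variants(values: dict[str, float]):
    """Mean and standard error across NEE-estimation variants.

    With a single variant the mean is returned and the SE is NaN (flagged
    undefined).  For two variants the SE equals half the absolute
    difference.
    """
    vals = np.asarray(list(values.values()), dtype=float)
    mean = float(vals.mean())
    if len(vals) < 2:
        return mean, float("nan")
    se = float(vals.std(ddof=1) / np.sqrt(len(vals)))
    return mean, se
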