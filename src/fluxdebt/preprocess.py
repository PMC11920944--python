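"""Flux quality filtering, day/night splitting, LAI compositing and gap fill.

Works on plain pandas DataFrames: half-hourly flux series carry columns
``timestamp``, ``nee``, ``rg``, ``tair`` and a ``qc`` flag
(``ok`` | ``range_removed`` | ``missing``); 8-day LAI series carry
``date`` and ``lai``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .periods import assign_periods

QC_OK = "ok"
QC_RANGE = "range_removed"
QC_MISSING = "missing"

NEE_RANGE = (-100.0, 100.0)
RG_THRESHOLD = 50.0


def filter_range(flux: pd.DataFrame, lo: float = NEE_RANGE[0],
                 hi: float = NEE_RANGE[1]) -> pd.DataFrame:
    """Flag NEE outside the open interval (lo, hi) as ``range_removed``.

    Original values are preserved; only the ``qc`` flag changes, so the
    operation is idempotent.  Out-of-range here means |NEE| >= 100 with the
    defaults (values beyond +/-100 µmol m-2 s-1 are physically implausible
    half-hourly CO2 fluxes).
    """
    if len(flux) == 0:
        raise ValueError("empty flux series")
    if lo >= hi:
        raise ValueError(f"lo must be < hi, got ({lo}, {hi})")
    out = flux.copy()
    nee = out["nee"].to_numpy(dtype=float)
    if "qc" not in out.columns:
        out["qc"] = QC_OK
    missing = ~np.isfinite(nee)
    bad = np.isfinite(nee) & ((nee <= lo) | (nee >= hi))
    qc = out["qc"].to_numpy(dtype=object)
    qc[missing & (qc == QC_OK)] = QC_MISSING
    qc[bad] = QC_RANGE
    out["qc"] = qc
    return out


def retained(flux: pd.DataFrame) -> pd.DataFrame:
    """Records that survived filtering (qc == ok)."""
    return flux[flux["qc"] == QC_OK]


def split_daynight(flux: pd.DataFrame, rg_threshold: float = RG_THRESHOLD):
    """Boolean (day, night) masks from incoming shortwave radiation.

    Day is strictly Rg > threshold; records at exactly the threshold go to
    night, so the masks partition all records with Rg defined.
    """
    rg = flux["rg"].to_numpy(dtype=float)
    defined = np.isfinite(rg)
    if not defined.any():
        raise ValueError("no records with rg defined")
    day = defined & (rg > rg_threshold)
    night = defined & ~day
    return day, night


def coverage(usable: np.ndarray, mask: np.ndarray) -> float:
    """Fraction of mask records that are usable; 0.0 for an empty mask."""
    n = int(np.sum(mask))
    if n == 0:
        return 0.0
    return float(np.sum(usable & mask)) / n


def composite_lai(lai8: pd.DataFrame, calendar: pd.DataFrame) -> pd.DataFrame:
    """Aggregate an 8-day LAI series to the 24-day calendar by maximum.

    An 8-day value belongs to the period containing its composite start
    date.  Periods with no valid value are left missing (NaN) and flagged.
    Returns the calendar with ``lai`` and ``filled`` columns appended.
    """
    out = calendar.copy()
    lai = np.full(len(calendar), np.nan)
    if len(lai8):
        idx = assign_periods(pd.DatetimeIndex(lai8["date"]), calendar)
        vals = lai8["lai"].to_numpy(dtype=float)
        for i in range(len(calendar)):
            v = vals[(idx == i) & np.isfinite(vals)]
            if len(v):
                lai[i] = v.max()
    out["lai"] = lai
    out["filled"] = False
    return out


def gapfill_linear(lai: pd.DataFrame, max_gap: int) -> pd.DataFrame:
    """Fill interior LAI gaps of up to ``max_gap`` periods by interpolation.

    Linear interpolation between the flanking observed values; longer gaps
    and leading/trailing gaps are left missing.  Filled entries are flagged.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    out = lai.copy()
    vals = out["lai"].to_numpy(dtype=float).copy()
    filled = out.get("filled", pd.Series(False, index=out.index)).to_numpy().copy()
    obs = np.flatnonzero(np.isfinite(vals))
    if len(obs) < 2:
        warnings.warn("fewer than 2 observed LAI values; nothing to interpolate")
        return out
    for left, right in zip(obs[:-1], obs[1:]):
        gap = right - left - 1
        if 0 < gap <= max_gap:
            frac = np.arange(1, gap + 1) / (gap + 1)
            vals[left + 1:right] = vals[left] + frac * (vals[right] - vals[left])
            filled[left + 1:right] = True
    out["lai"] = vals
    out["filled"] = filled
    return out
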