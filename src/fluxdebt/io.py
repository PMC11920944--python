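"""Read and write the pipeline's CSV dialects.

Flux series use AmeriFlux base-name columns (TIMESTAMP_START in
YYYYMMDDHHMM, NEE, SW_IN, TA, -9999 for missing); LAI series are plain
``date,lai`` (optionally ``pixel_id`` and a ``qa_pass`` flag); parameter
tables are tidy CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -9999.0
_FLUX_COLS = {"NEE": "nee", "SW_IN": "rg", "TA": "tair"}


def write_ameriflux(flux: pd.DataFrame, path) -> None:
    """Write a half-hourly flux series as AmeriFlux-style CSV."""
    ts = pd.DatetimeIndex(flux["timestamp"])
    out = pd.DataFrame({
        "TIMESTAMP_START": ts.strftime("%Y%m%d%H%M"),
        "TIMESTAMP_END": (ts + pd.Timedelta(minutes=30)).strftime("%Y%m%d%H%M"),
    })
    for col, name in _FLUX_COLS.items():
        vals = flux[name].to_numpy(dtype=float)
        out[col] = np.where(np.isfinite(vals), vals, MISSING)
    out.to_csv(path, index=False)


def read_ameriflux(path) -> pd.DataFrame:
    """Read an AmeriFlux-style CSV into the pipeline's flux frame.

    -9999 becomes NaN; records are kept in timestamp order and the ``qc``
    flag is initialized (``missing`` where NEE is absent, else ``ok``).
    """
    raw = pd.read_csv(path, dtype={"TIMESTAMP_START": str})
    ts = pd.to_datetime(raw["TIMESTAMP_START"], format="%Y%m%d%H%M")
    flux = pd.DataFrame({"timestamp": ts})
    for col, name in _FLUX_COLS.items():
        if col in raw.columns:
            vals = raw[col].to_numpy(dtype=float)
            flux[name] = np.where(vals == MISSING, np.nan, vals)
        else:
            flux[name] = np.nan
    flux = flux.sort_values("timestamp", ignore_index=True)
    flux["qc"] = np.where(np.isfinite(flux["nee"]), "ok", "missing")
    return flux


def write_lai(lai: pd.DataFrame, path) -> None:
    lai.to_csv(path, index=False, date_format="%Y-%m-%d")


def read_lai(path) -> pd.DataFrame:
    """Read an 8-day LAI CSV; rows failing an optional qa_pass flag go NaN."""
    raw = pd.read_csv(path, parse_dates=["date"])
    if "qa_pass" in raw.columns:
        raw.loc[~raw["qa_pass"].astype(bool), "lai"] = np.nan
    return raw


def write_params(fits: pd.DataFrame, path, site: str = "") -> None:
    """Write per-period parameter fits as tidy CSV (one row per estimate)."""
    rows = []
    for _, r in fits.iterrows():
        for var, status_col, rmse_col, n_col in [
                ("qy", "lrc_status", "lrc_rmse", "lrc_n_obs"),
                ("amax", "lrc_status", "lrc_rmse", "lrc_n_obs"),
                ("reco", "lrc_status", "lrc_rmse", "lrc_n_obs"),
                ("rb", "trc_status", "trc_rmse", "trc_n_obs"),
                ("e0", "trc_status", "trc_rmse", "trc_n_obs")]:
            rows.append({
                "site": site, "year": r["year"], "period": r["period"],
                "variable": var, "estimate": r[var], "n_obs": r[n_col],
                "rmse": r[rmse_col], "status": r[status_col],
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
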