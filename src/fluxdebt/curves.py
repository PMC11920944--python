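"""Light- and temperature-response curve models and per-period fits.

Daytime net ecosystem exchange (NEE, µmol CO2 m-2 s-1, negative = uptake)
follows a Michaelis-Menten type light response curve (LRC)

    NEE = QY * Amax * Rg / (QY * Rg + Amax) + Reco

with quantum yield QY (initial slope, µmol J-1, <= 0), light-saturated
assimilation Amax (asymptote, <= 0) and ecosystem respiration Reco as the
intercept (>= 0).  Nighttime respiration follows the Lloyd-Taylor /
Reichstein temperature response curve (TRC)

    Reco = rb * exp(E0 * (1/(Tref - T0) - 1/(Tair - T0)))

with base respiration rb at Tref = 15 degC and temperature sensitivity E0;
T0 is held at -46.02 degC.

Fits use bounded trust-region nonlinear least squares on 24-day periods and
are refused (not raised) when data coverage is below the 40% rule or the
parameters are unidentifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .preprocess import coverage as _coverage
from .preprocess import split_daynight

TREF = 15.0
T0 = -46.02

#: initial values and (lower, upper) bounds; the LRC Amax start is the
#: sign-corrected mirror of the printed +10, which lies outside its bounds
LRC_X0 = (-0.01, -10.0, 1.0)
LRC_BOUNDS = ((-0.4, -60.0, 0.0), (0.0, -0.01, 100.0))
TRC_RB_X0 = 100.0
TRC_BOUNDS = ((0.0, 50.0), (1000.0, 400.0))

OK = "ok"
REFUSED_COVERAGE = "refused_coverage"
REFUSED_IDENTIFIABILITY = "refused_identifiability"
FAILED = "failed"


def predict_lrc(rg, qy: float, amax: float, reco: float):
    """Evaluate the light response curve at incoming shortwave ``rg`` (W m-2)."""
    rg = np.asarray(rg, dtype=float)
    if np.any(rg < 0):
        raise ValueError("rg must be non-negative")
    denom = qy * rg + amax
    if np.any(np.abs(denom) < 1e-300):
        raise ZeroDivisionError("QY*Rg + Amax vanishes; parameters out of range")
    return qy * amax * rg / denom + reco


def predict_trc(tair, rb: float, e0: float):
    """Evaluate the temperature response curve at air temperature ``tair`` (degC)."""
    tair = np.asarray(tair, dtype=float)
    if np.any(tair <= T0):
        raise ValueError(f"tair must exceed T0 = {T0} degC")
    return rb * np.exp(e0 * (1.0 / (TREF - T0) - 1.0 / (tair - T0)))


@dataclass
class LRCParams:
    qy: float
    amax: float
    reco: float
    n_obs: int
    rmse: float
    converged: bool
    status: str = OK
    period: object = None
    stderr: np.ndarray | None = field(default=None, repr=False)

    @property
    def ok(self) -> bool:
        return self.status == OK and self.converged

    def as_array(self) -> np.ndarray:
        return np.array([self.qy, self.amax, self.reco])


@dataclass
class TRCParams:
    rb: float
    e0: float
    n_obs: int
    rmse: float
    converged: bool
    status: str = OK
    period: object = None
    tref: float = TREF
    t0: float = T0
    stderr: np.ndarray | None = field(default=None, repr=False)

    @property
    def ok(self) -> bool:
        return self.status == OK and self.converged

    def as_array(self) -> np.ndarray:
        return np.array([self.rb, self.e0])


def _stderr(res, n: int, p: int) -> np.ndarray:
    """Asymptotic standard errors from the solver Jacobian."""
    if n <= p:
        return np.full(p, np.nan)
    try:
        jtj = res.jac.T @ res.jac
        cov = np.linalg.inv(jtj) * (2.0 * res.cost / (n - p))
        return np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        return np.full(p, np.nan)


def _solve(residual, x0, bounds, n_obs):
    res = least_squares(residual, x0, bounds=bounds, method="trf",
                        max_nfev=1000, xtol=1e-10, ftol=1e-10, gtol=1e-10)
    rmse = float(np.sqrt(2.0 * res.cost / n_obs))
    return res, rmse


def fit_lrc(nee, rg, period=None, min_coverage: float = 0.4,
            coverage: float | None = None, x0=LRC_X0) -> LRCParams:
    """Fit the light response curve to daytime NEE in one period.

    ``coverage`` is the fraction of expected daytime records present; fits
    below ``min_coverage`` are refused with a distinct status rather than
    raised.
    """
    nee = np.asarray(nee, dtype=float)
    rg = np.asarray(rg, dtype=float)
    keep = np.isfinite(nee) & np.isfinite(rg)
    nee, rg = nee[keep], rg[keep]
    refused = LRCParams(np.nan, np.nan, np.nan, n_obs=len(nee), rmse=np.nan,
                        converged=False, period=period)
    if coverage is not None and coverage < min_coverage:
        refused.status = REFUSED_COVERAGE
        return refused
    if len(nee) < 4:
        refused.status = REFUSED_COVERAGE
        return refused

    def residual(x):
        return predict_lrc(rg, *x) - nee

    res, rmse = _solve(residual, x0, LRC_BOUNDS, len(nee))
    qy, amax, reco = res.x
    return LRCParams(qy, amax, reco, n_obs=len(nee), rmse=rmse,
                     converged=bool(res.success), period=period,
                     status=OK if res.success else FAILED,
                     stderr=_stderr(res, len(nee), 3))


def fit_trc(nee, tair, period=None, min_coverage: float = 0.4,
            coverage: float | None = None, rb0: float = TRC_RB_X0) -> TRCParams:
    """Fit the temperature response curve to nighttime NEE in one period.

    The E0 start is the mean nighttime NEE clamped into its own bounds
    [50, 400].  Fits with fewer than 3 distinct temperatures are refused as
    unidentifiable.
    """
    nee = np.asarray(nee, dtype=float)
    tair = np.asarray(tair, dtype=float)
    keep = np.isfinite(nee) & np.isfinite(tair)
    nee, tair = nee[keep], tair[keep]
    refused = TRCParams(np.nan, np.nan, n_obs=len(nee), rmse=np.nan,
                        converged=False, period=period)
    if coverage is not None and coverage < min_coverage:
        refused.status = REFUSED_COVERAGE
        return refused
    if len(nee) < 3:
        refused.status = REFUSED_COVERAGE
        return refused
    if len(np.unique(np.round(tair, 10))) < 3:
        refused.status = REFUSED_IDENTIFIABILITY
        return refused

    e0_start = float(np.clip(np.mean(nee), TRC_BOUNDS[0][1], TRC_BOUNDS[1][1]))

    def residual(x):
        return predict_trc(tair, *x) - nee

    res, rmse = _solve(residual, (rb0, e0_start), TRC_BOUNDS, len(nee))
    rb, e0 = res.x
    return TRCParams(rb, e0, n_obs=len(nee), rmse=rmse,
                     converged=bool(res.success), period=period,
                     status=OK if res.success else FAILED,
                     stderr=_stderr(res, len(nee), 2))


def fit_periods(flux: pd.DataFrame, calendar: pd.DataFrame,
                rg_threshold: float = 50.0,
                min_coverage: float = 0.4) -> pd.DataFrame:
    """Fit LRC (day) and TRC (night) parameters for every period.

    ``flux`` needs columns ``timestamp``, ``nee``, ``rg``, ``tair`` and a
    ``qc`` column (only ``qc == 'ok'`` records enter the fits).  Returns one
    tidy row per period with parameter estimates, n_obs, rmse and status.
    """
    from .periods import assign_periods

    day, night = split_daynight(flux, rg_threshold=rg_threshold)
    idx = assign_periods(flux["timestamp"], calendar)
    usable = (flux["qc"] == "ok").to_numpy() & flux["nee"].notna().to_numpy()
    rows = []
    for i, cal in calendar.iterrows():
        in_p = idx == i
        ref = (cal["year"], cal["period"])
        cov_day = _coverage(usable, in_p & day)
        cov_night = _coverage(usable, in_p & night)
        sel_d = in_p & day & usable
        sel_n = in_p & night & usable
        lrc = fit_lrc(flux.loc[sel_d, "nee"], flux.loc[sel_d, "rg"],
                      period=ref, min_coverage=min_coverage, coverage=cov_day)
        trc = fit_trc(flux.loc[sel_n, "nee"], flux.loc[sel_n, "tair"],
                      period=ref, min_coverage=min_coverage, coverage=cov_night)
        rows.append({
            "year": cal["year"], "period": cal["period"],
            "start": cal["start"], "end": cal["end"],
            "qy": lrc.qy, "amax": lrc.amax, "reco": lrc.reco,
            "lrc_n_obs": lrc.n_obs, "lrc_rmse": lrc.rmse,
            "lrc_status": lrc.status, "lrc_converged": lrc.converged,
            "rb": trc.rb, "e0": trc.e0,
            "trc_n_obs": trc.n_obs, "trc_rmse": trc.rmse,
            "trc_status": trc.status, "trc_converged": trc.converged,
            "day_coverage": cov_day, "night_coverage": cov_night,
        })
    return pd.DataFrame(rows)
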