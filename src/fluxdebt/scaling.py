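"""Scale carbon-exchange parameters across a landscape via LAI.

A least-squares response model links each per-period parameter to leaf
area index, time since disturbance, forest structure class and mean air
temperature.  Two link forms are supported and share one code path:

    identity-exp (default):  y = a1*exp(LAI) + a2*Time + a3*Structure
                                 + a4*Tair + a0
    log:                     y = exp(a1*LAI + a2*Time + a3*Structure
                                 + a4*Tair + a0)

Fitting acts on parameter magnitudes with the sign restored on output, so
least squares never has to cross zero for the negative-definite parameters
(QY, Amax).  Structure is coded tall = 0 / scrub = 1 (scrub: short-stature
stands with LAI <= 4; tall: closed canopy, LAI > 4), classified on
pre-disturbance LAI so no pixel changes class because of the storm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .curves import predict_trc
from .periods import assign_periods

STRUCTURE_LAI_THRESHOLD = 4.0
TALL, SCRUB = "tall", "scrub"

#: covariates entering each response model (intercept always included);
#: QY is modeled from structure and temperature only, rb from time and
#: structure only
DEFAULT_TERMS = {
    "reco": ("lai", "time", "structure", "tair"),
    "amax": ("lai", "time", "structure", "tair"),
    "qy": ("structure", "tair"),
    "rb": ("time", "structure"),
}
RESPONSE_SIGN = {"reco": 1.0, "amax": -1.0, "qy": -1.0, "rb": 1.0}
TIME_CAP_PERIODS = 61  # ~4 years of 24-day periods


def classify_structure(lai_reference: float) -> str:
    """Structure class from pre-disturbance LAI: scrub if LAI <= 4, else tall."""
    if lai_reference < 0:
        raise ValueError("LAI must be non-negative")
    return SCRUB if lai_reference <= STRUCTURE_LAI_THRESHOLD else TALL


def structure_code(structure) -> np.ndarray:
    """Numeric coding tall = 0, scrub = 1 (accepts labels or codes)."""
    arr = np.asarray(structure)
    if arr.dtype.kind in "OUS":
        return np.where(arr == SCRUB, 1.0, 0.0)
    return arr.astype(float)


def time_since_disturbance(period_starts, landfall_date,
                           cap: int = TIME_CAP_PERIODS) -> np.ndarray:
    """24-day periods elapsed since landfall: 0 before, capped at ~4 years."""
    starts = pd.DatetimeIndex(period_starts)
    landfall = pd.Timestamp(landfall_date)
    days = (starts.asi8 - landfall.value) / (86400 * 1e9)
    t = np.clip(np.floor(days / 24.0) + 1, 0, cap)
    return t.astype(float)


@dataclass
class ScalingModel:
    response: str
    link_form: str
    terms: tuple[str, ...]
    coef: dict[str, float]
    r_squared: float
    n_obs: int
    sign: float


class Prediction(NamedTuple):
    values: np.ndarray
    n_clipped: int


def _design(cov: pd.DataFrame, terms: tuple[str, ...], link_form: str) -> np.ndarray:
    cols = []
    for t in terms:
        x = cov[t].to_numpy(dtype=float) if t != "structure" \
            else structure_code(cov["structure"].to_numpy())
        if t == "lai" and link_form == "identity-exp":
            x = np.exp(x)
        cols.append(x)
    cols.append(np.ones(len(cov)))
    return np.column_stack(cols)


def fit_scaling(table: pd.DataFrame, response: str,
                link_form: str = "identity-exp",
                terms: tuple[str, ...] | None = None) -> ScalingModel:
    """Fit the scaling model for one response parameter.

    ``table`` needs a ``value`` column (the per-period parameter estimate)
    plus the covariates ``lai``, ``time``, ``structure`` and ``tair`` as
    required by ``terms``.  All response weights start at 1 for the
    identity link; the log link starts at zero weights with the intercept
    at log(mean |y|).
    """
    if link_form not in ("identity-exp", "log"):
        raise ValueError(f"unknown link_form {link_form!r}")
    terms = tuple(terms if terms is not None else DEFAULT_TERMS[response])
    keep = table["value"].notna()
    for t in terms:
        keep &= table[t].notna()
    data = table[keep]
    if "structure" in terms and len(np.unique(structure_code(
            data["structure"].to_numpy()))) < 2:
        raise ValueError("structure term requested but only one structure "
                         "class present")
    y = np.abs(data["value"].to_numpy(dtype=float))
    X = _design(data, terms, link_form)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design for {response}: collinear terms among "
            f"{terms + ('intercept',)}")

    if link_form == "identity-exp":
        x0 = np.ones(X.shape[1])
        def model(w):
            return X @ w
    else:
        x0 = np.zeros(X.shape[1])
        x0[-1] = np.log(max(y.mean(), 1e-12))
        def model(w):
            return np.exp(np.clip(X @ w, -700.0, 700.0))

    res = least_squares(lambda w: model(w) - y, x0, method="trf",
                        max_nfev=2000, xtol=1e-12, ftol=1e-12, gtol=1e-12)
    fitted = model(res.x)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    names = [("exp_lai" if (t == "lai" and link_form == "identity-exp") else t)
             for t in terms] + ["intercept"]
    return ScalingModel(response=response, link_form=link_form, terms=terms,
                        coef=dict(zip(names, (float(v) for v in res.x))),
                        r_squared=r2, n_obs=len(y),
                        sign=RESPONSE_SIGN[response])


def predict_params(model: ScalingModel, covariates: pd.DataFrame) -> Prediction:
    """Evaluate the fitted model on pixel/period covariates.

    Predicted magnitudes are clipped at zero (so Amax/QY stay non-positive
    and Reco/rb non-negative after the sign is restored); the number of
    clipped predictions is returned for diagnostics.
    """
    X = _design(covariates, model.terms, model.link_form)
    w = np.array([model.coef[n] for n in
                  [("exp_lai" if (t == "lai" and model.link_form == "identity-exp")
                    else t) for t in model.terms] + ["intercept"]])
    if model.link_form == "identity-exp":
        mag = X @ w
    else:
        mag = np.exp(np.clip(X @ w, -700.0, 700.0))
    n_clipped = int(np.sum(mag < 0))
    mag = np.clip(mag, 0.0, None)
    return Prediction(values=model.sign * mag, n_clipped=n_clipped)


def model_nee(params: pd.DataFrame, drivers: pd.DataFrame,
              variant: str = "lrc", rg_threshold: float = 50.0) -> pd.DataFrame:
    """Reconstruct half-hourly NEE from per-period parameters.

    ``params`` is a period calendar (``start``/``end``) with columns
    ``qy``, ``amax``, ``reco`` and, for the ``lrc_trc`` variant, ``rb`` and
    ``e0``.  Variant ``lrc`` applies the light response curve to all
    half-hours; ``lrc_trc`` applies it to daytime (Rg > threshold) and the
    temperature response curve at night.
    """
    if variant not in ("lrc", "lrc_trc"):
        raise ValueError(f"unknown variant {variant!r}")
    idx = assign_periods(drivers["timestamp"], params)
    if np.any(idx < 0):
        raise ValueError("drivers extend outside the parameter calendar")
    need = ["qy", "amax", "reco"] + (["rb", "e0"] if variant == "lrc_trc" else [])
    used = np.unique(idx)
    missing = [f"{params.iloc[i]['year']}-P{params.iloc[i]['period']}"
               for i in used
               if not np.all(np.isfinite(params.iloc[i][need].to_numpy(dtype=float)))]
    if missing:
        raise ValueError(f"missing parameters for periods: {', '.join(missing)}")
    rg = drivers["rg"].to_numpy(dtype=float)
    qy = params["qy"].to_numpy()[idx]
    amax = params["amax"].to_numpy()[idx]
    reco = params["reco"].to_numpy()[idx]
    # elementwise light response; a clipped Amax = 0 degenerates to Reco
    denom = qy * rg + amax
    safe = np.where(denom == 0.0, 1.0, denom)
    nee = np.where(denom == 0.0, 0.0, qy * amax * rg / safe) + reco
    if variant == "lrc_trc":
        tair = drivers["tair"].to_numpy(dtype=float)
        night = ~(rg > rg_threshold)
        rb = params["rb"].to_numpy()[idx]
        e0 = params["e0"].to_numpy()[idx]
        nee[night] = predict_trc(tair[night], rb[night], e0[night])
    return pd.DataFrame({"timestamp": drivers["timestamp"], "nee": nee,
                         "variant": variant})
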