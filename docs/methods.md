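# Methods

This note records the models implemented in `fluxdebt`, the assumptions
behind them, the choices made where the design was genuinely open, and
what the synthetic-data tests do and do not demonstrate about real data.

## Calendar and bookkeeping

All analysis runs on 24-day periods tiling each calendar year: period 1
starts January 1, periods 1–14 are 24 days, and period 15 absorbs the
remainder (29 days; 30 when a leap day is present in real inputs). The
simulator and the debt integration use a fixed 365-day year: timestamp
grids are built on real dates with every Feb 29 removed, and debt windows
are measured on a no-leap day-number scale so every landfall-anniversary
year spans exactly 365 × 48 half-hours. The alternative tiling (truncating
the year at day 360) was considered and rejected because it would leave
5–6 days of every year outside any period.

## Flux preprocessing

NEE outside the open interval (−100, 100) µmol CO₂ m⁻² s⁻¹ is flagged
`range_removed`; values are preserved and only the flag changes, making
the filter idempotent. Day is strictly Rg > 50 W m⁻², night Rg < 50;
records at exactly 50 go to night, which is conservative for the light
curve (a 50 W m⁻² record carries almost no light-response information but
would otherwise enter the fit as a daytime point). Coverage for the 40%
fit-refusal rule is computed against the half-hours of the period that
belong to the relevant mask (day or night), since the rule gates each fit
separately. LAI is composited per period by maximum and gap-filled
linearly for interior gaps up to a configurable number of periods
(default 2); edge gaps are never extrapolated because linear interpolation
needs two anchors.

## Response-curve fitting

Both curves are fit by bounded trust-region least squares
(`scipy.optimize.least_squares`, trf, max 1000 evaluations, tolerances
1e-10). The printed initial Amax of +10 lies outside its own bounds
(−60, −0.01); the sign-corrected mirror −10 is used. The TRC is the
Lloyd–Taylor exponential; the E0 start is the mean nighttime NEE clamped
into the E0 bounds [50, 400] because the raw mean usually falls below 50.
The rb start of 100 is far above realistic values (~1–3) but the bounded
solver is insensitive to it on every test problem; it is configurable.
Fits are *refused* — a status, not an exception — for coverage below 40%,
for fewer than 3 usable records, and for nighttime series with fewer than
3 distinct temperatures (E0 unidentifiable). Asymptotic standard errors
from the solver Jacobian accompany every fit; they are Wald-calibrated on
simulated data (95% intervals cover truth in ≥93% of 200 replicates at
noise sd 2 µmol m⁻² s⁻¹, n = 500).

## Relative non-stationarity

RN for a trailing window of 45 periods (~3 years) is the fitted change
over the window divided by the window mean. The regression includes one
seasonal harmonic pair (cos/sin at the annual period) alongside the
linear term, so the annual cycle is accounted for inside the slope
computation: an integer-cycle sinusoid of any phase yields |RN| < 1e-6,
while a plain OLS slope of a sinusoid is not zero. The change dx is slope
× window span (equivalently the fitted-line endpoint difference). Windows
containing any missing period are skipped rather than interpolated, so RN
reflects measured change only; a zero window mean leaves RN undefined
(flagged, not raised). A constant series gives RN = 0 under this
definition — the convention that "1 means stable" found in some
descriptions is not reproducible from the formula and is not used.
Thresholds are empirical percentiles (85/90/95, linear interpolation) of
|RN| over the entire record, computed per site and per variable, and
|RN| is used so both negative excursions (parameter drops) and positive
ones (respiration rebound) register. The impact duration is the time from
landfall to the *last* post-landfall period above the threshold,
interruptions included: this is the only reading under which durations
are guaranteed monotone in the threshold (a "first run" rule with any gap
tolerance can start later and last longer at a higher threshold).
Trailing windows are indexed by their end period, so post-landfall RN
reflects data entering the window after the storm; durations are
therefore upper-bounded by roughly the window length plus the physical
recovery time.

## Landscape scaling

Each response parameter is linked to covariates by one of two forms
sharing a single code path:

* identity link with exponential LAI covariate (default for
  `fit_scaling`): y = α₁·exp(LAI) + α₂·Time + α₃·Structure + α₄·Tair + α₀
* log link (default for the end-to-end landscape chain):
  y = exp(α₁·LAI + α₂·Time + α₃·Structure + α₄·Tair + α₀)

Fitting acts on parameter magnitudes with the sign restored on output, so
least squares never crosses zero for the negative-definite parameters;
predictions are clipped at zero magnitude and the clip count is reported
(clipping should touch well under 1% of pixels for in-range
configurations). Identity-link weights start at 1; the log link starts at
zero weights with the intercept at log(mean |y|), since unit start
weights overflow the exponential for realistic covariates. Term sets per
response: LRC Reco and Amax use all four covariates; QY uses structure
and temperature only; rb uses time and structure only. E0 has no spatial
model and is carried as the pooled mean of converged tower fits.
Structure is coded tall = 0 / scrub = 1 and classified once per pixel on
pre-disturbance LAI (scrub ≤ 4 < tall), so no pixel changes class because
of the storm. Time since disturbance counts 24-day periods from landfall,
0 before, capped at ~4 years. Pixels are abstract cells with a default
area of 250,000 m² (nominal 500 m cell).

The end-to-end landscape chain uses the log link because the generator's
parameter–LAI law is exponential (below) and the log link can represent
it exactly; the identity-exp form remains available and shares all code.
The time covariate is highly collinear with the LAI recovery trajectory:
with noisy fits its weight is poorly determined, and because it enters
the prediction for four years of post-storm periods, small spurious time
weights produce a visible drift in late-year landscape debt. This is an
estimation-variance property of the design, not a code defect; it is
visible in the acceptance script's noisy-chain numbers.

## Recovery debt

Debt is Σ(NEE_post − mean NEE_pre) per half-hour, converted at
1800 s × 12.011e-6 g C µmol⁻¹, so a constant +1 µmol m⁻² s⁻¹ weakening
over a 365-day year is +378.78 g C m⁻². Positive = debt, negative =
enhanced capture; the sign convention follows the reported-results usage
(a weakened sink accrues positive debt). The reference is the mean over
[landfall − 365 d, landfall), requiring ≥80% completeness by default.
Annual debts use landfall-anniversary years (calendar years would mix
pre- and post-storm months in year 1); the horizon defaults to 4 years
but is configurable. Gaps in a measured post-storm series may be filled
from a modeled-NEE variant; with none supplied they raise. "Recovery of
all lost carbon" is the first year whose cumulative debt is ≤ 0.
Landscape totals are area-weighted sums in Mt C (1 Mt = 10¹² g), with the
fraction of pixels in net enhanced capture reported alongside, since
landscape cancellation can hide local debts.

## Synthetic data

The simulator emulates a subtropical mangrove study design. Drivers are
deterministic: a half-sine radiation course over a fixed 06–18 h
photoperiod with a seasonal amplitude peaking at the summer solstice
(default peak 650 ± 200 W m⁻²), and air temperature as seasonal + diurnal
sinusoids around 24.5 °C (±4.5 seasonal, ±4 diurnal) — Everglades-like
values. LAI is sampled every 8 days: constant at baseline, a step drop at
landfall (default 50% of a 5.55 m² m⁻² canopy), then exponential
recovery with a 200-day e-folding time. The recovery form is a stand-in;
no claim is made that real canopies recover exponentially.

Carbon-exchange parameters derive from LAI through a configurable law.
The default is exponential in LAI for the Amax and Reco magnitudes,
anchored so the law passes through tall-forest means (Amax −32.14, Reco
7.49 µmol m⁻² s⁻¹ at LAI 5.55) and scrub means (−9.97, 1.76 at LAI 2.87);
QY (−0.1367 µmol J⁻¹), rb (3.22 µmol m⁻² s⁻¹) and E0 (107.43) are
constant, reflecting that quantum yield, nighttime base respiration and
temperature sensitivity show no canopy-loss response in disturbed
mangrove records. A saturating alternative (`SaturatingParamLaw`,
magnitudes ∝ 1 − exp(−0.5·LAI)) is provided for probing the scaling model
under a family it cannot represent; under that law both scaling links
misestimate landscape debt by tens of percent even without noise, which
is the expected behavior, not a defect. Within each 24-day period the
generating parameters are held constant at the law evaluated on the
period's maximum-composited LAI, which is what makes a noise-free run
exactly refittable (generative identity).

Noise is additive iid Gaussian on NEE (default sd 2 µmol m⁻² s⁻¹);
missingness is uniform at random (default 20%) plus an optional single
outage interval for testing the coverage rule. Landscape baselines come
from a two-mode Gaussian mixture (scrub-like 2.87 ± 0.5, tall-like
5.55 ± 0.5, equal weights) truncated at zero by redraw. In the landscape
chain the disturbance is structure-specific: tall pixels follow the tall
trajectory's relative drop and recovery while scrub pixels are
undisturbed, mirroring the observed scrub insensitivity to canopy loss.

What passing tests show: the estimators are exact on clean data, unbiased
and interval-calibrated under Gaussian noise, and the full chain
reproduces a known landscape debt trajectory when the scaling family
contains the generating law. What they do not show: robustness to
heteroscedastic or gap-structured flux error, u*-filtering and storage
effects, real MODIS QA artifacts, tidal/salinity drivers, or
non-exponential canopy recovery — none of which the simulator emulates.

## Problem sizes

Default experiments use a 7-year tower record (122,640 half-hours, 105
periods) with landfall late in year 3, 200 replicates for stochastic
recovery checks, 2,000-point null series for RN calibration, and a
1,000-pixel landscape integrated over one reference plus four post-storm
years; together these run in well under a minute of fitting time plus a
few seconds per landscape variant.
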