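# Methods

## Study design

The unit of analysis is one decedent. The case day is the date of death;
referent days are all days in the same calendar month and year sharing the
case day's ISO weekday, excluding the case day itself — always 3 or 4 of
them, before and after the event. Conditioning on one event per stratum
yields the conditional-logistic likelihood; exposure contrasts are entirely
within-month and within-weekday, so time-invariant subject covariates,
day-of-week patterns and seasonal/sub-seasonal trends at monthly resolution
are controlled by design. Residual *within-month* trends (smooth seasonal
drift across a 28–31-day window) are **not** removed by the design: with
the generator's winter-peaking mortality sinusoid (amplitude 0.1 on the log
scale) exactly in phase with the winter-peaking PM2.5 sinusoid, paired
simulations measured an upward offset of roughly +1 point per 10 µg/m³ in
the PM2.5 estimate. This is a real property of time-stratified referents
under perfectly collinear seasonal phases, and the reason the recovery
study defines its unconfounded worlds with the seasonal mortality term
switched off (the null-calibration study keeps it: the induced bias is far
below one per-replicate SE, so test size is unaffected).

## Exposure features

Each pollutant enters as the unweighted moving average of lags 0–2 (the lag
window is configurable per pollutant; a 0–1 window is exercised in tests as
an alternative). Temperature enters as same-day level, its square, and the
lag 1–3 moving average; absolute humidity as same-day level and the lag 1–3
moving average. Negative exposure controls are each pollutant's lead-1
(day-after-death) value. Missing panel days are never imputed: a referent
row with any incomplete feature is dropped; a death whose case row is
incomplete is dropped (counted in the log); strata reduced below one
referent, or in which every feature is constant across rows, are dropped as
non-informative.

## Conditional logistic regression

Implemented from the likelihood up: exact analytic gradient and observed
information, Newton–Raphson with step-halving from β = 0 (the likelihood is
concave, so accepted steps never decrease it). Convergence when the
max-norm of the gradient falls below 1e-8 (on the internally standardised
scale) or the relative log-likelihood change falls below 1e-10; maximum 50
iterations; non-convergence raises by default. Numerical choices:

- per-stratum max-subtraction inside the log-sum-exp;
- features are centred within stratum and scaled to unit variance inside
  the solver. The conditional likelihood is invariant to stratum-constant
  shifts and coefficients are rescaled back afterwards, so estimates are
  unchanged while raw Kelvin-squared columns no longer poison the
  conditioning of the information matrix;
- columns with no within-stratum variation, and rank-deficient designs, are
  rejected with the offending feature names (smallest-eigenvalue test on
  the standardised Gram matrix at β = 0);
- the covariance is the inverse observed information at the optimum; the
  Wald multiplier is fixed at 1.959964.

Effects are reported per 10-unit increment only at the reporting layer
(`100·(exp(10β) − 1)`); coefficients are carried on the native per-unit
scale internally to avoid double-scaling.

## Negative-control layer

**Lead-1 diagnostic and joint fit.** The main model includes the lead-1
terms; their coefficients are reported as negative-exposure-control
diagnostics. **Coefficient-difference correction:** β_exposure − β_lead,
with variance V_ee + V_ll − 2V_el taken from the joint-fit covariance (an
independence approximation is available but labelled as such). This is
unbiased when the omitted confounder loads equally on the exposure feature
and the lead feature; because the exposure feature is a 3-day average while
the lead is a single day, exact equality requires the confounder to move
slowly relative to the lag window.

**Stage 1 (surrogate).** Daily regional counts of the negative-control
cause are modelled with an in-repo IRLS Poisson log-linear fit on the
pollutant moving averages, the lead-1 terms, the weather terms, periodic
seasonal harmonics (2 by default) and region intercepts. The fitted mean Ŵ
per (date, region) is the confounder surrogate — always finite and
nonnegative by construction.

**Stage 2.** The conditional-logistic model is refit with Ŵ (lag 0 only)
added. Two open choices were pinned here:

- *Leads are excluded from stage 2 by default.* In the linear analogue,
  Ŵ is a linear combination of exposure and lead (plus terms that are
  stratum-constant), so a stage-2 design containing exposure, lead **and**
  Ŵ has no identifying direction left for the confounder proxy; with the
  lead excluded, the span of {exposure, Ŵ} equals the span of
  {exposure, lead} and the exposure coefficient is unconfounded. Pilot
  simulations showed essentially no bias reduction with leads retained and
  60–90% reduction with them excluded. `keep_leads=True` remains available.
- *Ŵ enters untransformed by default*; `log_surrogate=True` enters log Ŵ,
  which is exactly linear in the stage-1 predictors and can behave better
  when counts are sparse.

A Ŵ that is constant within every stratum cancels from the conditional
likelihood and is dropped automatically, making the stage-2 fit identical
to the joint fit in that degenerate case.

## Synthetic worlds

The generator is first-class, tested code; its defaults define the
desk-scale study conditions (50 regions × 3 years × 2 expected
deaths/region/day ≈ 110k deaths; the simulation studies use a reduced
12-region × 18-month × 1/day world so that hundreds of replicates run in
minutes).

- **Pollutants:** annual sinusoidal mean plus AR(1) deviations with
  cross-correlated innovations (default correlation 0.4), floored at zero.
  Means, SDs and seasonal phases match multi-state US daily surfaces
  (PM2.5 10.4 µg/m³ winter-peaking, O3 37.7 ppb summer-peaking, NO2
  21.2 ppb winter-peaking). `noise_sds` are innovation SDs; the marginal
  SD is `noise/√(1−ρ²)`.
- **Weather:** temperature is an annual sinusoid (mean 284 K, amplitude
  12 K, peak day 205) plus AR(1) noise; absolute humidity is a
  Clausius–Clapeyron-like exponential of same-day temperature
  (0.0073·exp(0.06·(T−284)) g/cm³) plus noise, floored at a small positive
  value.
- **Confounder U:** AR(1) per region with coefficient 0.9 (weather-like
  persistence) and unit marginal SD. It enters every pollutant at lag 0
  with loading λ_e and at lead 1 with loading λ_e·ratio (ratio 1 by
  default — the equal-loading assumption of the difference correction;
  set it away from 1 to study violations), and enters the log mortality
  rate with loading λ_m. The slow persistence is what makes U's loading on
  a 3-day moving average approximately equal to its loading on the lead-1
  value, the regime the correction is designed for.
- **Deaths:** region-day counts are Poisson with log-rate
  `log(baseline) + Σ_p β_p(MA02_p − mean) + λ_m·U + seasonal`, a
  winter-peaking annual sinusoid of amplitude 0.1 on the log scale.
  Exposure terms are centred at the grand mean so `baseline_rate` keeps
  its meaning. Counts are expanded to individual records; covariates (sex,
  race, age group, education, urbanicity) are drawn independently of
  day-within-month, consistent with the case-crossover premise that
  subject covariates are stratum-constant. Cardiovascular and respiratory
  records come from parallel Poisson streams with configurable effect
  multipliers (1.1 and 1.6); the NAFLD stream carries the U and seasonal
  terms but **no** pollutant term. The first two days of the range have no
  computable moving average and generate no deaths (logged).
- The planted PM2.5 truth is ln(1.0073)/10 per µg/m³, i.e. 0.73% per
  10 µg/m³ on the lag 0–2 moving average.

What the generator does **not** emulate: within-region spatial exposure
heterogeneity (1 km grids), exposure-model measurement error, long-term
pollution trends, demographic structure in risk (covariates are decoration,
not risk factors), and harvesting/mortality displacement. Passing recovery
tests therefore demonstrates the correctness of the estimator stack under
the stated generating model, not robustness to those real-data features.

## Simulation studies (validation module)

- *Recovery:* 200 unconfounded replicates with the planted 0.73% effect;
  checks Wald CI coverage ≥ 93% and a mean within 3 Monte-Carlo SEs of
  truth.
- *Confounding:* 50 replicates with λ_e = 2, λ_m = 0.4, ratio 1 and a
  negative-control fraction of 0.15. These magnitudes were fixed as the
  study scenario so that the omitted-confounder bias is large relative to
  Monte-Carlo error and the stage-1 fit has usable signal at desk scale;
  the checks are that the naive bias is detectable, both diagnostics fire
  on average, and each correction removes at least half of the naive bias.
- *Null calibration:* 200 replicates with all effects and loadings zero;
  the pooled rejection rate of the three pollutant Wald tests is checked
  against a band about four binomial SDs wide (the pollutants are
  correlated within a replicate, so the 600 tests are not independent).

Replicate seeds are derived deterministically from a single master seed.

## Secondary analyses

- **Low-exposure restriction:** a stratum is retained iff *every* case and
  referent day's value of each restricted pollutant lies strictly below its
  threshold (WHO guideline defaults: 25 µg/m³ PM2.5, 50 ppb O3, 106.4 ppb
  NO2); rows are never dropped individually, preserving the matched set. A
  case-day-only rule is available behind a flag, and the US-standard
  thresholds (35/70/100) can be supplied as config values.
- **Urbanicity:** a region is urban iff its density strictly exceeds the
  death-weighted 25th percentile of the study population's density, where
  the percentile linearly interpolates the weight-expanded sample (with
  equal weights this is the conventional sample percentile; with all
  densities equal everything is rural).
- **Subgroups:** per-level stratified fits are independent, so contrasts
  use z = (β₁−β₂)/√(SE₁²+SE₂²). No multiplicity adjustment is applied;
  p-values are reported raw.
- **Temperature sensitivity:** temperature features are expanded to
  region-group-specific columns (stratum rows share a region, so the
  interaction is stratum-consistent); with a single group the model reduces
  exactly to the main fit.

## Known limitations

- The two-stage estimator inherits stage-1 sampling noise: with sparse
  negative-control counts the surrogate direction is poorly estimated and
  the correction is partial. The difference correction is the more stable
  of the two at small scale.
- Separation (infinite MLE) is reported as non-convergence rather than
  detected a priori.
- The cause-specific streams are independent Poisson processes, so the
  all-cause total is Poisson but cause shares fluctuate; multipliers scale
  log rate ratios, not shares.
- Calendar gaps in the exposure panel silently shrink strata (by the
  missing-data rules above); a panel with systematic weekday gaps would
  bias referent availability.
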