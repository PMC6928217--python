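# Methods

## Problem and approach

Satellite sea-surface temperature (SST) products drive the operational coral
bleaching heat-stress metric, the Degree Heating Week (DHW), but a satellite
pixel reads the ocean skin layer while corals live metres to tens of metres
below it. Under summer stratification a moored subsurface temperature
recorder (STR) is systematically cooler than the SST above it, so applying
the surface bleaching threshold directly to logger data suppresses apparent
subsurface stress and manufactures spurious "depth refugia". The package
implements the remedy end to end:

1. reduce logger records to nighttime (local sunset to sunrise) daily means,
   paired by date with nighttime SST values;
2. estimate the seasonal STR−SST bias per site — the mean of daily
   differences during the climatologically warmest month (summer) and the
   month six months offset (winter);
3. shift the surface MMM threshold (maximum of the twelve monthly mean
   climatologies) by the summer bias: `MMM_sub = MMM_surf + bias`, with bias
   defined as STR − SST so that a cooler logger yields a cooler threshold;
4. accumulate DHW under three input combinations — surface MMM on SST,
   surface MMM on STR (kept diagnostic-only), and the bias-adjusted MMM on
   STR;
5. detect heat-stress events as maximal runs of dates where any variant is
   above zero, recording per-variant maxima and truncation at record edges;
6. fit the three inferential models: bias vs depth (Gaussian LMM), event
   severity vs depth (zero-inflated negative binomial GLMM), and the
   surface-to-subsurface accuracy ratio (Gaussian model on log2 ratios).

## Conventions that the standard product definitions leave open

* **Night definition.** Night is computed from solar elevation at the site
  (low-order solar-position series, no refraction): a sample is nocturnal
  when the sun is below the horizon. A fixed local window ("18:00-06:00") is
  available for controlled tests. A night spans two dates and is attributed
  to the date it ends on (the sunrise date). Local time comes from the
  site's longitude (UTC offset = round(lon/15)) unless metadata provides an
  offset; no timezone database is consulted.
* **Continuity.** "At least 365 days of continuous data" is read strictly:
  the longest run of consecutive non-missing dates must reach `min_days`
  (default 365). A configurable `max_gap_days` (default 0) can bridge short
  gaps without counting them toward the run.
* **Climatology.** Month means are computed month-first (average within each
  year-month, then across years) so unevenly covered years carry equal
  weight. MMM ties resolve to the earliest month. The surface warmest month
  is applied at depth; the STR-observed warmest month is reported only as a
  diagnostic.
* **Seasonal bias pooling.** All qualifying days across years are pooled
  (day-weighted), matching "mean of daily differences"; the alternative
  (per-year month means averaged) is not used. The reported SE is the sample
  SD of daily biases over sqrt(n); it is for tables only — the mixed models
  refit from per-site means.
* **DHW accumulation.** HotSpot = T − MMM; days with HotSpot ≥ 1 °C
  contribute their full anomaly to an 84-day rolling sum divided by 7
  (°C-weeks). Missing days contribute zero but the value is reported missing
  when window coverage falls below 90% (configurable); the first 83 dates
  are undefined. 4 and 8 °C-weeks are the interpretive bleaching /
  severe-bleaching levels.
* **Events.** Runs split wherever all three variants are zero or missing;
  missing DHW counts as zero for splitting but flags the event. "Severe"
  means ≥ 4 °C-weeks by the surface or the bias-adjusted metric — the
  unadjusted variant never decides severity. Events are per site; depth-bin
  summaries are derived tables, not event units.
* **Accuracy ratio zero cases.** Subsurface-zero events are pinned at 800%
  (log2 = +3), surface-zero at 12.5% (log2 = −3), both excluded from
  statistics; double zeros count as 100% (log2 = 0) and are included.

## Statistical models

**Bias vs depth.** Response: per-site seasonal mean bias (°C). Fixed effect:
depth (modelled per metre, reported per 10 m). Random intercepts: island
nested in region, fit as a Gaussian mixed model (statsmodels MixedLM with a
variance component for island). Geography is strictly nested, so nested
rather than crossed intercepts are the default.

**Severity vs depth.** Response: event-maximum bias-adjusted DHW rounded to
the nearest integer °C-week, a zero-heavy overdispersed count. The model is
a zero-inflated negative binomial regression with log link, `log mu = b0 +
b1*depth + u_site + v_island + w_region`, independent Gaussian random
intercepts, constant zero-inflation probability on the logit scale, and NB
dispersion k (var = mu + mu^2/k). Estimation is written in-house: for fixed
parameters the random effects are profiled out by a damped-Newton search for
the penalized mode with analytic first and second derivatives, the marginal
likelihood is formed by a one-point Laplace approximation (penalized
log-likelihood at the mode minus half the log-determinant of the mode's
Hessian), and the marginal is maximized by L-BFGS-B with up to three
jittered restarts (seed-controlled; restarts stop early when they reproduce
the incumbent optimum). Wald SEs come from a central-difference Hessian of
the negative log marginal at the optimum. With no random effects and no
zero inflation the marginal is the exact fixed-effects NB likelihood, which
is cross-checked in tests against statsmodels' independent NB implementation
(agreement to 1e-3 relative). ZIP, plain NB/Poisson and Gaussian variants
are available through the same interface for the family comparison;
Gaussian fits fail the zero-inflation diagnostic on severity-like data,
which is why ZINB is the default.

**Accuracy ratio.** Included log2 ratios are modelled with a Gaussian mixed
model (random intercepts over whichever of region/island/site have at least
two levels; ordinary least squares when none do, as in ungrouped synthetic
ratios). The intercept back-transforms exactly as 2^estimate × 100% with ±1
SE bounds transformed the same way; its two-sided test against 0 is a test
of mean ratio = 100%.

**Diagnostics.** Simulation-based residual checks in the randomized-quantile
style: replicate datasets are simulated unconditionally from the fitted
model; each observation's randomized PIT residual is uniform under a correct
model. Four checks: KS uniformity; overdispersion (mean squared deviation
scaled by simulated variance, two-sided simulation p); zero inflation
(observed zero count against its simulated distribution; continuous
responses are rounded to the response's integer grid first); and
heteroscedasticity (Brown-Forsythe spread test of residuals across fitted
halves).

## Synthetic archive

The generator emulates the statistical structure of a multi-site Pacific
logger archive. Surface daily (nighttime) temperature = base mean (27 °C) +
seasonal cosine (amplitude 2 °C, peak at the warmest month, September by
default) + monthly AR(1) "ENSO" anomaly (sd 0.25 °C, lag-1 coefficient 0.9,
interpolated to days) + boxcar warm events (default 1/yr, 60 d, +2 °C;
placement can be fixed for bookkeeping tests) + white noise (0.05 °C). The
logger measures the same field plus a depth bias whose per-10 m slope is
modulated between the summer (−0.15 °C) and winter (−0.028 °C) endpoints by
the weight (1 + cos of the phase distance from the warmest month)/2 — the
within-year shape between the two documented endpoints is a modelling
choice — plus Gaussian site/island/region intercepts (sd 0.05 °C each).
Sub-daily samples (30 min default, valid range 5 min–12 h) add a diurnal
cosine peaking at local noon, centred so the fixed-window nighttime mean is
unbiased, and sensor noise (0.01 °C, well above the ±0.002 °C instrument
accuracy). The daily logger level applies noon-to-noon so a whole night
samples one day's level, keeping nighttime means exactly comparable to the
daily SST series. Whole days drop out with probability `gap_prob` (1%).
Depths span 1–38 m evenly but are shuffled across the hierarchy so depth is
not confounded with island or region. Each site consumes a random stream
keyed by (seed, site index): adding sites never perturbs existing ones, and
identical configurations are bit-reproducible.

Not emulated: internal waves, mixing, heat-budget physics, horizontal
gradients within a satellite pixel, or any biological bleaching response.
Passing tests therefore demonstrate that the estimators recover what they
claim to estimate under the stated stochastic structure — not that the
structure captures every property of real reef records.

Truth-level shortcut generators draw directly the per-site seasonal biases
(hierarchical Gaussian) and per-event ZINB severities the mixed models
consume. Parameter-recovery studies use them: 100 archipelagos of 400 sites
for the bias-slope study (mean estimate within ±0.02 °C/10 m of truth, 95%
CI coverage in [90%, 99%]), 200 replicates for the type-I-error check
(rejection in [2%, 9%] at alpha = 0.05), and 1,000-event tables for ZINB
recovery. Full time-series runs (nighttime reduction through event
detection) use single sites and 12-site archipelagos; these sizes keep the
default suite and the acceptance script to a few minutes while leaving the
statistical checks well-powered.

## Numerical choices and degenerate inputs

* Rolling DHW agrees with an explicit per-window summation oracle to 1e-9
  °C-weeks; the bias-adjustment identity DHW(T, MMM+b) = DHW(T−b, MMM) holds
  to the same tolerance (floating-point association prevents exact bitwise
  equality).
* MixedLM fits run with REML and fall back from L-BFGS to Powell; singular
  or non-converged fits set `converged=False` rather than raising.
* ZINB inner Newton: Cholesky with escalating ridge on indefiniteness,
  backtracking line search, gradient tolerance 1e-11 (tight so the outer
  finite differences stay clean). Outer parameters are bounded (log k in
  [−7, 9], logit pi in [−12, 8], log sigma in [−8, 3]).
* Empty pairings warn and return empty; an all-zero severity response, a
  month with no qualifying days, and double bias adjustment raise errors.
* Depths outside (0, 40] m warn but are accepted; latitude/longitude are
  validated to their physical ranges.

## I/O scope

All interfaces are plain CSV (logger samples, daily SST, site metadata,
bias/DHW/event/accuracy tables, truth tables) plus YAML configs and JSON fit
reports; the CSV dialects written by the simulator are exactly the dialects
the readers consume.

## Known limitations

* The MMM construct assumes a meaningful seasonal cycle; in
  equatorial-Pacific-like regimes (weak seasonality, strong interannual
  variability — reachable in the generator by shrinking the seasonal
  amplitude and inflating the AR(1) term) the warmest-month concept is
  fragile, and no alternative baseline is implemented.
* The zero-inflation probability is constant (no covariates on the zero
  part), matching the modelling contract; the severe-only subset largely
  removes zeros, in which case the ZI component is weakly identified and
  the plain NB family is the sensible choice.
* The accuracy-ratio severity scale and the GLMM slope are reported on the
  scales produced by the models here (log2 and log-link respectively);
  back-transformed slopes in response units are not produced.
* Event onset-lag analytics and depth-binned event merging are out of scope;
  depth bins are summaries only.
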