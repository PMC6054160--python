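# Methods

## The measurement model

The raw observable is a census series: repeated counts of active bee
nests, or of inflorescences with at least half their flowers open, in a
fixed plot across one season, indexed by integer day-of-year (DOY).
Censuses are sparse (about weekly), so every phenology statistic is a
convention on how to read a continuous season off a sparse grid:

* **start / end** — first and last census with a positive count.  Days
  between two positive censuses count as present (the closed interval
  convention): activity is assumed continuous between detections, which
  matches how presence bars are drawn from such data.  The alternative —
  counting only census days themselves — would make "days present"
  depend on census cadence rather than on the season.
* **peak** — census day with the highest count; ties resolve to the
  earliest such day so results are deterministic.
* **50 %-activity day** — the cumulative count curve is taken as the
  running sum at each census (each census's mass dated wholly to its
  day), linearly interpolated between censuses; the statistic is the
  first crossing of half the season total, with an exact hit at a census
  returning that census day.  The crossing is clamped to
  `[start, end]`: when the first active census alone carries at least
  half the total, raw interpolation from the preceding zero census would
  date the 50 % point before any activity was observed.  A consequence
  of the running-sum convention is that an odd-length symmetric series
  dates its 50 % point slightly before the middle census; the even,
  exact-hit case lands on the midpoint census.
* **mean date** — the average of `(start+end)/2` and the 50 %-activity
  day, a centre-of-season statistic that is robust to a long sparse tail
  on one side of the curve.

Percent overlap and asynchrony compare each focal plot with the *pooled*
opposite-role plots of its site: presence days are unioned (the union
may be non-contiguous), and the site resource mean date is, by default,
the unweighted mean of the resource plots' mean dates.  The alternative
— the mean date of the pooled activity curve, which weights plots by
abundance — is implemented behind the `asynchrony-convention` switch
(`plot-mean` / `pooled-curve`); the plot-mean default treats plots as
replicates, consistent with reporting per-plot means ± SD.  Presence and
overlap use integer days; the mean-date statistics and asynchrony stay
fractional and are written to 2 decimals.  Seasons are assumed to sit
inside one calendar year; a wrapped season is rejected at validation.

## The cue model

Each plot's microclimate is reduced to seasonal summaries over a closed
DOY window, by default 32–151 (February 1 – May 31, the measurement
campaign): min/max/mean soil temperature at 1 cm and at 25 cm — the
near-surface environment and the shallowest depth at which the
diapausing bees sit — plus mean volumetric water content.  Phenophase
dates are then modelled per guild as

    date_ij = x_ij' beta + u_i + e_ij,   u_i ~ N(0, var_site),  e_ij ~ N(0, var_resid)

a random intercept per site with a fixed mean.  Predictors enter on
their raw measurement scale (°C, VWC fraction): the interaction
coefficients are therefore large numbers, and slopes comparable across
models are produced post hoc as marginal slopes at the sample mean of
the other covariate.

**Selection.**  Stage 1 compares eight single-predictor models (null,
mean moisture, six temperature summaries) by AICc; stage 2 takes the
winning temperature summary T\* and compares `T*`, `T* + M`,
`T* + M + T*:M`.  If the null or moisture model happens to outrank every
temperature model, T\* is still the best temperature summary, so the
stage-2 nested sequence is always constructible; the stage-1 ranking
(with ΔAICc and a co-best flag at <1 unit) records the actual winner.
AICc uses `k` = number of fixed coefficients + 2 variance components,
including boundary fits with the site variance at zero, and is undefined
(an error) when `n <= k + 1`.

**Likelihood.**  All AICc values come from full maximum likelihood:
REML likelihoods are not comparable across fixed-effect structures, and
the candidate set varies exactly there.  A `reml` switch exists for
benchmarking against software whose mixed-model default is REML.  The
solver profiles the likelihood over the variance ratio
`lambda = var_site/var_resid`, with closed-form GLS coefficients and a
closed-form profiled residual variance at each step; the profile is
maximized by a coarse log-spaced grid (including the `lambda = 0`
boundary) followed by golden-section refinement to 1e-8 on the
log-likelihood.  A site variance estimated at the boundary is reported
as zero with a `singular` flag, never as an error; at that boundary the
ML solution coincides with the closed-form fixed-effects-only fit, which
is what gets reported.  With a single site (or on request) the site
variance is constrained to zero outright and the fit is the closed-form
ML linear regression — this is the contract that the mixed fit must
reproduce ordinary least squares exactly in the degenerate case.

**Standard errors.**  With five sites and 17–30 plots the naive ML
covariance of the fixed effects is noticeably anticonservative (simulated
coverage of nominal 95 % intervals near 85 %).  Reported standard errors
therefore use the REML variance estimates with the Kenward–Roger
adjusted covariance; for the linear covariance structure used here the
second-derivative term of the adjustment vanishes, and the
variance-parameter covariance is the inverse expected REML information.
Simulated coverage at the default study design is ≈ 91–92 %; the
remaining gap to 95 % is the fixed 1.96 multiplier meeting a t-like
sampling distribution with roughly 9–14 effective degrees of freedom,
which is irreducible at this design size.  OLS-fallback standard errors
use the df-corrected residual variance `RSS/(n-p)`.

**R².**  Marginal and conditional R² are variance partitions:
`r2m = var_fixed / (var_fixed + var_site + var_resid)` and
`r2c = (var_fixed + var_site) / (same)`, with `var_fixed` the sample
variance (ddof = 1, the R `var()` convention) of the fixed-effect linear
predictor across plots.

Plots missing any abiotic summary are excluded from model fitting with a
logged warning, never imputed, so every candidate model for a guild sees
the same plot set and the AICc comparison stays valid.

## The synthetic-data generator

The generator reproduces the statistical structure the analysis assumes,
with defaults set to the monitored system: 5 sites; 3 bee plots at three
sites and 4 at two (17 total); 6 flower plots per site (30 total);
censuses every 6 ± 1.5 days (gaps rounded, minimum one day; the first
visit jittered up to two days, scaled by the gap SD so a deterministic
cadence yields identical schedules) across DOY 32–190.

*Microclimate.*  All plots share a linear warming ramp at 1 cm
(7.5 °C + 0.075 °C/day); a plot differs by an additive thermal offset
(site SD 0.4 °C plus plot SD 0.3 °C) and a multiplicative ramp-rate
factor (CV 0.12).  The rate factor is what makes the seasonal *maximum*
vary partly independently of the seasonal *mean* — without it the six
temperature summaries would be nearly collinear across plots and
model selection would have no identifiable truth to find.  The 25 cm
series is a damped (×0.6), lagged (8 days) transform of the 1 cm
deterministic course with smaller measurement noise (0.25 vs 1.0 °C);
moisture declines linearly from 0.32 VWC at 0.0013/day around a plot
offset (SD 0.025) and is clipped to [0.01, 0.45].  Measurements are
emitted only at the plot's census days up to the end of the summary
window, as in a field campaign.

*Phenology.*  A plot's true season start is linear in its *realized*
abiotic summaries — the same quantities the analysis later recomputes
from the emitted measurement rows — so slope recovery is free of
errors-in-variables attenuation by construction.  Bees couple to the
seasonal maximum 25 cm temperature at −15.3 days/°C and flowers to the
seasonal mean at −6.6 days/°C, with opposite-signed moisture effects
(−240.5 and +272.7 days per VWC unit); site intercept SD 3 days, plot
residual SD 3 days.  The intercepts (363 bee, 107 flower) centre the
mean starts near DOY 95 and 104, i.e. early April, with starts ranging
late March–early May.  Activity follows a symmetric Gaussian bell
(sigma = duration/5, zero outside `[start, start + duration]`,
duration ~ 70 ± 8 days truncated below at two census intervals) scaled
to a peak intensity of 50; observed counts are Poisson draws of the bell
at the census days.  `count_noise="none"` emits the rounded bell itself
for noise-free checks.  The bell shape, the Poisson count noise and the
peak intensity are artifact choices — only unimodality and the census
cadence are given by the study design.

A true start outside the census season is an error (the design could
never observe it); activity running past the last census is simply
right-censored by the grid, as in real monitoring.  Two derived
configurations re-centre the intercepts by the mean contribution of the
removed effects so seasons stay observable: `temperature_only_config`
(moisture effects off; the known-truth scenario for selection-power
checks) and `null_config` (no abiotic effects; the calibration scenario
in which the null model should stay within 2 AICc units of any spurious
winner in most replicates).

*What passing tests show, and what they do not.*  The generator draws
plot effects independently given site, uses a common ramp shape, and has
no temporal autocorrelation in measurement noise, no detection-
probability model, no skewed activity curves, and no spatial covariance
between neighbouring plots.  Calibration results (slope recovery bias
within Monte-Carlo error, interval coverage ≈ 0.91–0.92, stage-1 power
≈ 97 % at the default effect size) therefore certify the *pipeline* —
that the estimators recover what the model assumes when the assumptions
hold — not the field system; real data can violate these assumptions in
all the listed ways.

## Numerical conventions and edge cases

* Observation-free degenerate inputs raise named errors: an all-zero
  census series ("no activity", naming the plot), an empty focal
  presence set, fewer than two in-window abiotic records (naming the
  plot), AICc with `n <= k + 1`.
* A site with only one role is skipped from the overlap table with a
  warning, not an error.
* Peak ties resolve to the earliest day; the stage-2 temperature term on
  a stage-1 tie (<1 AICc) is the lower-AICc model, with the co-best set
  recorded in the output.
* One integer seed drives a `numpy` `SeedSequence` tree; each pipeline
  stage draws from its own spawned stream, so adding a stage never
  perturbs earlier stages' draws, and a run manifest (seed +
  configuration + versions) suffices to reproduce any run byte for byte.
* Output CSVs: phenology/overlap tables at 2 decimals; model and
  marginal-slope tables at 4, because raw-scale interaction coefficients
  and variance components lose meaning at 2.

## Known limitations

* No random slopes, temporal autocorrelation, degree-day accumulation,
  spatial covariance, detection modelling, or multi-model averaging of
  coefficients — all out of scope by design.
* The AICc ranking assumes every candidate sees the same plots; the
  pipeline enforces this by dropping summary-less plots up front.
* With five sites the site-variance estimate is weak; boundary
  (singular) fits are common under weak site signal and are reported,
  flagged, rather than suppressed.
* Interval coverage at the default design is ≈ 91–92 % against a 95 %
  nominal level; see the standard-error discussion above.
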