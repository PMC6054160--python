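# phenosync

Phenological synchrony between a flowering plant and its ground-nesting
bee pollinator, from plot-level census counts and soil microclimate
measurements.

The package is written for field ecologists who monitor a plant and a
pollinator guild through a season — counting inflorescences in bloom and
active bee nests in fixed plots every few days, and measuring soil
temperature (near the surface and at bee-overwintering depth) and soil
moisture on the same visits — and who want to answer two questions:

1. **How synchronous are the two species now?**  Per plot: what
   percentage of its active days are covered by the opposite guild's
   resources at the same site, and how far apart are their seasonal mean
   dates?
2. **Which abiotic summary best predicts the timing**, and how steeply
   would timing shift per degree of warming?

## Statistics

For each plot-season the activity curve `(doy_i, count_i)` yields start,
peak (highest count, earliest on ties) and end dates, the interpolated
day at which cumulative activity first reaches 50 % of the season total,
and the mean date

```
mean date = ( (first DOY + last DOY)/2  +  DOY of 50 % activity ) / 2 .
```

Against the pooled presence days of all opposite-role plots at the same
site (union of their `[start, end]` intervals), each focal plot gets

```
percent overlap = 100 * (# focal days also covered by site resources) / (# focal days)
asynchrony      = | mean date(focal) - mean date(site resources) |        [days]
```

Timing is then regressed on per-plot seasonal summaries of soil
temperature at 1 cm and 25 cm depth (min/max/mean, February–May) and
mean volumetric soil moisture, with a linear mixed model

```
date_ij = beta0 + beta_T * T_j + beta_M * M_j + beta_TM * T_j * M_j + u_i + e_ij
u_i  ~ N(0, var_site)       (random intercept per site)
e_ij ~ N(0, var_resid)
```

Candidate models are ranked by AICc (`AIC + 2k(k+1)/(n-k-1)`, `k` =
fixed coefficients + 2 variance components) in two stages: eight
single-predictor models first, then — for the winning temperature
summary — the nested sequence `T`, `T+M`, `T+M+T:M`.  Likelihoods are
full ML so AICc is comparable across fixed-effect structures; standard
errors come from the REML variance estimates with the Kenward–Roger
small-sample adjustment.  Fit quality is reported as marginal /
conditional R² (variance explained by fixed effects alone vs fixed plus
site effects), and interaction models are summarised by the marginal
slope at the sample mean of the other covariate (days per °C at average
moisture, and days per VWC unit at average temperature).

A synthetic-season generator (`phenosync.synth`) emulates the study
design — 5 sites, 17 bee plots, 30 flower plots, censuses every
6 ± 1.5 days, unimodal activity curves whose timing is linear in the
abiotic summaries with a site random intercept — so the whole pipeline
can be exercised, and its statistical calibration verified, without any
field data.

## Worked example

Simulate a season, run the full pipeline, and print the digest:

```
$ phenosync all --seed 1 --out demo_run
run complete: demo_run
$ phenosync report --dir demo_run
== overlap / asynchrony ==
  role  n_plots  overlap_mean  overlap_sd  asynchrony_mean  asynchrony_sd
   bee       17         96.42        6.52             7.28           5.47
flower       30         96.60        6.66             6.26           5.20
== stage-1 winning cue per phenophase ==
  role phenophase   model     aicc    r2m    r2c
   bee      start  T1_ave 124.9467 0.7151 0.7151
   bee       peak T25_max 121.6111 0.7595 0.7595
   bee        end T25_max 125.9966 0.6959 0.6959
flower      start   M_ave 196.0434 0.3232 0.7542
flower       peak  T1_ave 224.5141 0.4144 0.4242
flower        end  T1_ave 221.0603 0.4285 0.4413
== marginal slopes at covariate means ==
  role phenophase               model temperature_summary  temp_slope_days_per_degC  moisture_slope_days_per_vwc
   bee       peak T25_max+M+T25_max:M             T25_max                  -13.5875                    -144.8755
...
```

Reading this: in the simulated season bee plots were active with flowers
present on 96.4 % of their active days (mean over 17 plots) and their
mean dates sat 7.3 days from the site flowering mean; the bee peak was
best predicted by seasonal maximum 25 cm soil temperature, with nesting
advancing ~13.6 days per °C at average soil moisture.  In any single
season the stage-1 winner for some phenophases can differ from the
generative cue — moisture variation masks part of the temperature
signal, which is why calibration claims below rest on replicated runs.

The run directory contains `phenology.csv`, `overlap.csv`,
`overlap_summary.csv`, `models.csv` (the tidy two-stage AICc table, one
row per coefficient), `marginal_slopes.csv`, the simulated inputs, and a
`run_manifest.json` that records the seed and configuration; rerunning
with the same seed reproduces every file byte for byte.  The same
subcommands work on real data: `phenosync metrics --census census.csv`
and `phenosync cues --census census.csv --abiotic abiotic.csv` accept
plain CSVs with columns `site,plot,role,doy,count` and
`site,plot,doy,temp_1cm,temp_25cm,moisture`.

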