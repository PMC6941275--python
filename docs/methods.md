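# Methods

## Design and estimation

The package estimates short-term exposure-outcome associations from a daily
count series using the time-stratified case-crossover design in its Poisson
formulation: a quasi-Poisson regression of the daily count on exposure terms,
a public-holiday indicator and a fixed effect for every (year, calendar
month) stratum, with offset `log(Population_ye)` (year-end population).
Within-month self-matching removes secular trend, seasonality and any
confounder that is stable over a month; a seven-year series yields 84 strata.
Day-of-week adjustment is available as a switch (`AnalysisSettings
.day_of_week`) but is off by default, matching the written model: whether the
month-stratified design alone or additional day-of-week terms were used in
the original analyses is ambiguous, and the default follows the equation as
written.

Two estimation routes are implemented and tested against each other:

* **indicators** — explicit stratum dummy columns, fitted by statsmodels'
  Poisson GLM (IRLS). This is the reference route.
* **absorb** — the conditional (case-crossover) formulation: given the other
  coefficients, each stratum's effect has the closed form
  `s_g = log(sum_g y / sum_g mu_0)`, so the stratum block is profiled out
  inside IRLS and the remaining covariates are within-stratum
  weighted-centered (Frisch-Waugh). The two routes agree to ~1e-13 on the
  non-stratum coefficients; the agreement is itself an acceptance check,
  because it is the equivalence that justifies estimating a case-crossover
  by stratum-fixed-effect Poisson regression. The absorbed route is roughly
  60x faster (no 100+-column solve per iteration) and is used in the
  simulation loops.

Dispersion is estimated from the Pearson statistic, phi = X^2 / (n - p),
with p counting all estimated parameters including stratum effects; the
coefficient covariance is phi times the inverse Fisher information. Q-AIC is
`-2*loglik/phi + 2p` with the Poisson log-likelihood at the estimate. When
ranking nested candidates, the dispersion of the most complex candidate is
applied to all of them so that every Q-AIC shares one scale — a convention,
since quasi-likelihood does not fix the comparison scale by itself.
Aliased columns are dropped greedily in first-kept order and reported.

## Cross-basis construction

Each exposure enters through a cross-basis: row *t* holds
`sum_l R_j(x_{t-l}) C_k(l)` over all pairs of exposure-basis and lag-basis
columns, ordered with the exposure index outer. Defaults are df 3 in both
dimensions, maximal lag 14 days for pollutants and 3 days for meteorology.

Natural cubic splines are built from the cubic B-spline basis with the
second-derivative-at-boundary constraints imposed by QR projection, and are
continued linearly beyond the boundary knots. Knot placement follows the
de-facto DLNM convention: exposure-dimension interior knots at equally
spaced quantiles (df 3: 33.3rd/66.7th percentiles) with boundary knots at
the observed min/max; lag-dimension interior knots at equally spaced values
on the log-lag scale with boundary 0..L. The exposure basis has no
intercept (the model intercept and strata absorb level). The lag basis
*does* include an intercept: without it the span cannot contain a
lag-constant effect profile, so a truth with uniform lag weights would be
inestimable and cumulative contrasts biased; with it, df 3 means intercept
plus two columns (one interior knot), and the column count bookkeeping
(df_var x df_lag = 9) is unchanged. The basis contract is its span, which
is what the tests pin down (projection of linear functions, brute-force
cross-basis oracle), not individual column values.

Rows with incomplete lag history (the first `maxlag` days) are flagged and
excluded from fits rather than imputed.

## Effects

All reported quantities are linear contrasts of a cross-basis coefficient
block: lag-specific log-RR at a single lag, cumulative log-RR over a lag
window (the sum of the single-lag contrasts), and cumulative
exposure-response curves over a grid. CIs use the delta method on the log
scale with the exact normal multiplier 1.959964; the delta-method SE is
verified against the SD of 10,000 multivariate-normal coefficient draws.
Extreme-influence tables contrast the 1st and 99th percentiles of the
analyzed (post-mask) exposure series against its median — the post-mask
convention keeps the contrast internally consistent with the fitted rows;
at n ~ 2,500 the pre/post-mask difference in percentiles is negligible.
Exposure values outside the observed range are rejected rather than
extrapolated. Percentiles use linear interpolation between order statistics
throughout.

## Model selection

Single-pollutant models are screened first; a pollutant is carried forward
when any extreme-contrast cell's CI excludes 1 at any stated lag window
(this operationalizes "no significant single-pollutant association" as the
exclusion path — e.g. a null pollutant like CO drops out here). Candidate
multi-pollutant models are all pairs among the survivors whose Spearman
|r| <= 0.60; more strongly correlated pairs are excluded outright. Each
reported pollutant uses its lowest-Q-AIC candidate.

## Synthetic data

The generator emulates a seven-year (2,557-day) registry study in a
subtropical coastal city. Five pollutant series (SO2, NO2, PM10, CO, O3)
are seasonal AR(1) processes loaded on a common latent daily AR(1) factor,
truncated at 0.1 ug/m3; the shared factor gives the positive
cross-pollutant Spearman correlations, and opposite seasonal phase plus
negative loadings make temperature and humidity anticorrelate with
pollution (O3 peaks in the warm season with a small loading, so it is only
weakly correlated with the primary pollutants). Marginal means (~12, 46,
56, 1.2, 53 ug/m3) and spreads echo published descriptive tables for such a
city without attempting to match them numerically.

Counts are negative-binomial with mean
`mu_t = Population * exp(baseline + seasonal baseline + sum_i f_i + gamma*holiday)`
and variance `dispersion * mu_t` (Poisson when dispersion = 1); quasi-Poisson
has no generative form, and mean-variance-parameterized NB is the standard
stand-in. Defaults: baseline rate giving ~25 events/day in a population of
10.5 million, dispersion 2.5 and a winter-peaking baseline sinusoid
(amplitude 0.10 on the log scale), which together give a marginal count SD
near 10. Seasonality deliberately enters both the exposures and the
baseline rate so the stratum terms have genuine confounding to remove.
Holidays are fixed calendar offsets each year (Jan 1-3, May 1-3, Oct 1-7)
with a log-rate effect of 0.05 so the holiday coefficient is recoverable.

Effect surfaces are piecewise-linear: J-shaped (hinge above a threshold
near the 75th percentile) for SO2, NO2 and PM10, V-shaped around the median
for O3, null for CO, each spread over lags 0..14 by nonnegative weights
summing to one (exponentially decaying, scale 4 days, by default). The
exact cumulative log-RR of any contrast is available in closed form
(`true_cumulative_log_rr`), which is what the recovery experiments compare
against. Subgroup counts are independent binomial thinnings of the total
(59.5% male, 48.4% elderly): subgroup analyses are exercised for mechanics,
not for effect-heterogeneity recovery, and the generator cannot plant
subgroup-specific effects. A burn-in of `maxlag` days is simulated before
the first output day so every output row has a full lag history; the exact
pre-noise mean `mu_t` is stored for oracle checks.

What the generator does *not* emulate: spatial (district/station)
structure and exposure measurement error, reporting artifacts (weekday
effects in ascertainment), long-term population drift, and subgroup effect
heterogeneity. Passing recovery tests therefore show the estimator is
correct under the model's own assumptions, not that those assumptions hold
in any particular registry.

## Validation experiments and problem sizes

The acceptance suite (and `scripts/acceptance.py`) uses: 50 random series
for the cross-basis triple-loop oracle; a 6-day, 2-stratum fixture for the
brute-force likelihood oracle (BFGS + Nelder-Mead polish of the written
Poisson likelihood); a 731-day study for the route-equivalence check; 200
replicate 2,557-day studies each for null calibration (dispersion in
[0.9, 1.1], type-I error of the 99th-vs-median cumulative RR at 5% +/- 3%)
and for parameter recovery (mean cumulative log-RR within 0.05 of the
planted truth, 95% CI coverage within 95% +/- 3%); and 50 studies for the
averaged-curve shape checks. The recovery experiment plants the J surface
in SO2 *only* (threshold 14.5 ug/m3, slope 0.035 per ug/m3, uniform lag
weights, true cumulative log-RR ~ 0.34 at the 99th-vs-median contrast over
lag 0-12): with correlated co-pollutant effects also present, a
single-pollutant model absorbs part of them — that is confounding the
design expects the analyst to address through multi-pollutant models, not
an estimator defect, so the recovery estimand is isolated by construction.

## Numerical choices and limitations

* IRLS convergence: coefficient-change and deviance-change tolerance 1e-10,
  100-iteration cap, error on non-convergence.
* Strata with an all-zero response are retained; in the absorbed route their
  profiled effect is -inf and their rows contribute nothing, which matches
  the explicit-indicator limit.
* The spline hinge-approximation bias of a df-3 exposure basis against a
  piecewise-linear truth is small but nonzero (~0.01-0.03 on the log-RR
  scale in the recovery experiment) and is the main contributor to coverage
  sitting at the low end of the nominal band.
* Q-AIC comparisons across non-nested pollutant sets use each model's own
  dispersion; only within one pollutant's candidate set is a common
  (largest-model) dispersion imposed.
* No penalized splines, no conditional-logistic estimation, no
  robust/sandwich variances, no autocorrelation corrections, no
  attributable-fraction computations.
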