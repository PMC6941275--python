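# lagrisk

Distributed-lag non-linear modelling of daily event counts in a
time-stratified case-crossover design.

`lagrisk` is for environmental epidemiologists studying the short-term,
possibly delayed and non-linear association between daily ambient exposures
(air pollutants, temperature) and the daily onset count of an acute outcome
such as ischemic stroke. It implements the analysis pipeline used in daily
time-series studies of pollution and stroke: quasi-Poisson regression with
calendar-stratum fixed effects, cross-basis (DLNM) exposure terms, relative
risks at extreme exposure percentiles, Q-AIC model selection with a
collinearity screen, subgroup analyses, and sensitivity scans — together with
a synthetic-data generator whose ground truth is known exactly, so the whole
pipeline can be validated by parameter recovery.

## The model

Daily counts are modelled as

    Y_t ~ quasiPoisson(mu_t),
    log(mu_t / Population_ye) = alpha
        + sum_i cb(Pollutant_{i,t}; df_var, maxlag, df_lag)
        + cb(Temp_t; 3, 3, 3) + cb(RH_t; 3, 3, 3)
        + gamma * Holiday_t + lambda_stratum

where `cb()` is a cross-basis: the tensor product of a natural cubic spline
in the exposure dimension (df 3, knots at the 33.3rd/66.7th percentiles) and
one in the lag dimension (df 3, log-spaced knots, maximal lag 14 days for
pollutants, 3 for meteorology). The stratum fixed effects (year x calendar
month) implement the time-stratified case-crossover design, removing trend,
seasonality and slow confounders by self-matching within a month.
Overdispersion is absorbed by the Pearson-estimated dispersion phi, which
scales the coefficient covariance and enters model comparison through
Q-AIC = -2*loglik/phi + 2p.

Effects are reported as cumulative relative risks over lag windows
(lag 0-1, 0-6, 0-8, 0-10, 0-12, 0-13, 0-14) contrasting the 99th (or 1st)
exposure percentile against the median, with delta-method 95% CIs on the log
scale. Pollutant pairs with Spearman |r| > 0.60 are never entered in one
model.

## Worked example

```python
import dataclasses
import numpy as np
import lagrisk as lr
from lagrisk import pipeline
from lagrisk.simulate import EffectSurfaceSpec, uniform_weights

# study conditions with a known J-shaped truth planted in SO2 only
cfg = lr.default_config(seed=0)
effect = EffectSurfaceSpec("J", threshold_high=14.5, slope_high=0.035,
                           lag_weights=uniform_weights(14))
cfg = dataclasses.replace(cfg, pollutants=tuple(
    dataclasses.replace(p, effect=effect) if p.name == "so2"
    else dataclasses.replace(p, effect=EffectSurfaceSpec("null"))
    for p in cfg.pollutants))

series = lr.generate_series(cfg).series        # 2,557 consecutive days
fit, cbs = pipeline.fit_model(series, ["so2"])  # quasi-Poisson + strata

v = series["so2"].to_numpy()[14:]               # analyzed (post-mask) series
med, hi = np.quantile(v, [0.50, 0.99])
est = lr.cumulative_rr(fit, cbs["so2"], hi, med, (0, 12))
truth = lr.true_cumulative_log_rr(cfg, "so2", hi, med, (0, 12))

print(f"dispersion phi = {fit.dispersion:.2f}, Q-AIC = {fit.qaic:.1f}")
print(f"SO2 99th vs median ({hi:.2f} vs {med:.2f} ug/m3), cumulative over lag 0-12:")
print(f"  estimated RR = {est.rr:.2f} (95% CI {est.lo:.2f}, {est.hi:.2f})")
print(f"  true planted RR = {np.exp(truth):.2f}")
```

prints

```
dispersion phi = 2.49, Q-AIC = 7846.5
SO2 99th vs median (26.17 vs 12.28 ug/m3), cumulative over lag 0-12:
  estimated RR = 1.45 (95% CI 1.23, 1.70)
  true planted RR = 1.42
```

i.e. a 2,557-day study with overdispersed counts (phi ~ 2.5) recovers the
planted cumulative relative risk of the 99th-vs-median SO2 contrast to well
within its confidence interval.

The same pipeline is scriptable end to end (`simulate`, `describe`, `fit`,
`report`, `sensitivity`):

```
lagrisk simulate --seed 3 --out series.csv
lagrisk report --seed 3 --out-dir study_out/
lagrisk sensitivity --input-csv series.csv --pollutant so2 --out-dir sens/
```

`report` writes descriptives, the Spearman matrix, the single-pollutant
screen, the model plan after the collinearity rule, per-subgroup
extreme-influence tables (total / male / female / elderly / adult) and
exposure-response curves, all as CSV.

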