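"""Synthetic daily series with the structure the case-crossover DLNM assumes.

The generator emulates a seven-year urban registry study: seasonal, mutually
correlated pollutant concentration series; meteorology anticorrelated with
pollution; and overdispersed daily event counts driven by a *known* nonlinear
lagged log-relative-risk surface.  Because the true surface is stored with the
configuration, the exact cumulative log-RR of any exposure contrast is
available for parameter-recovery tests (:func:`true_cumulative_log_rr`).

Count model: mean mu_t = Population_ye * exp(baseline + seasonal baseline +
sum_i f_i(lagged exposures) + holiday effect), variance = dispersion * mu_t
via a negative-binomial draw (plain Poisson when dispersion is 1).  A burn-in
of ``maxlag`` days is simulated before the first output day so every output
row has a full lag history.

Effect surfaces are piecewise-linear hinge functions:

* ``J``: f(x) = slope_high * max(x - threshold_high, 0) — risk rises above a
  threshold only (the shape seen for primary gaseous/particulate pollutants);
* ``V``: a J plus slope_low * max(threshold_low - x, 0) — risk rises on both
  sides of a low-risk window (the ozone pattern);
* ``null``: identically zero.

The surface for pollutant i contributes sum_l f_i(x_{i,t-l}) * w_i(l) to the
log rate, with nonnegative lag weights w summing to one.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "EffectSurfaceSpec",
    "PollutantSpec",
    "SeasonalSpec",
    "SimulationConfig",
    "SimulatedStudy",
    "default_config",
    "generate_series",
    "true_cumulative_log_rr",
    "write_series_csv",
    "read_series_csv",
]

DAYS_PER_YEAR = 365.25
EXPOSURE_FLOOR = 0.1  # ug/m3; spline bases need a finite positive range

GROUP_COLUMNS = ("total", "male", "female", "elderly", "adult")


@dataclass(frozen=True)
class EffectSurfaceSpec:
    """Piecewise-linear exposure-response truth times a lag-weight profile."""

    shape: str = "null"  # one of {"null", "J", "V"}
    threshold_high: float = 0.0
    slope_high: float = 0.0
    threshold_low: float = 0.0
    slope_low: float = 0.0
    lag_weights: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        if self.shape not in ("null", "J", "V"):
            raise ValueError(f"unknown shape {self.shape!r}")
        w = np.asarray(self.lag_weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("lag weights must be nonnegative")
        if self.shape != "null" and abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("lag weights must sum to 1")
        if self.shape == "V" and self.threshold_low > self.threshold_high:
            raise ValueError("threshold_low must not exceed threshold_high")

    @property
    def maxlag(self) -> int:
        return len(self.lag_weights) - 1

    def f(self, x):
        """Exposure-response function in log-RR units (vectorized)."""
        x = np.asarray(x, dtype=float)
        if self.shape == "null":
            return np.zeros_like(x)
        out = self.slope_high * np.maximum(x - self.threshold_high, 0.0)
        if self.shape == "V":
            out = out + self.slope_low * np.maximum(self.threshold_low - x, 0.0)
        return out


def decaying_weights(maxlag: int, scale: float = 4.0) -> tuple[float, ...]:
    """Exponentially decaying lag weights over 0..maxlag, summing to 1."""
    w = np.exp(-np.arange(maxlag + 1) / scale)
    return tuple(w / w.sum())


def uniform_weights(maxlag: int) -> tuple[float, ...]:
    return tuple(np.full(maxlag + 1, 1.0 / (maxlag + 1)))


@dataclass(frozen=True)
class SeasonalSpec:
    """Seasonal AR(1) series: mean + amplitude*cos(2*pi*(doy-peak)/365.25)
    + loading*latent_factor + AR(1) noise."""

    mean: float
    seasonal_amplitude: float
    ar_coefficient: float
    noise_sd: float
    peak_day: float = 15.0  # day-of-year of the seasonal maximum
    shared_factor_loading: float = 0.0

    def __post_init__(self) -> None:
        if not abs(self.ar_coefficient) < 1:
            raise ValueError("|ar_coefficient| must be < 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclass(frozen=True)
class PollutantSpec:
    name: str
    series: SeasonalSpec
    effect: EffectSurfaceSpec = field(default_factory=EffectSurfaceSpec)


@dataclass(frozen=True)
class SimulationConfig:
    start_date: dt.date
    n_days: int
    seed: int
    pollutants: tuple[PollutantSpec, ...]
    temp_spec: SeasonalSpec
    rh_spec: SeasonalSpec
    baseline_log_rate: float
    baseline_seasonal_amplitude: float
    dispersion: float
    population_by_year: dict[int, int]
    holiday_effect: float = 0.0
    holiday_dates: frozenset[dt.date] = frozenset()
    factor_ar: float = 0.7
    male_prob: float = 0.595
    elderly_prob: float = 0.484
    maxlag: int = 14  # burn-in length; all output rows have full lag history

    def __post_init__(self) -> None:
        if self.n_days < 366:
            raise ValueError("n_days must be >= 366")
        if self.dispersion < 1:
            raise ValueError("dispersion must be >= 1")
        for p in self.pollutants:
            if p.effect.shape != "null" and p.effect.maxlag > self.maxlag:
                raise ValueError(
                    f"effect lag weights of {p.name} exceed the burn-in maxlag"
                )
        last = self.start_date + dt.timedelta(days=self.n_days - 1)
        for year in range(self.start_date.year, last.year + 1):
            if year not in self.population_by_year:
                raise ValueError(f"no population entry for year {year}")

    def pollutant(self, name: str) -> PollutantSpec:
        for p in self.pollutants:
            if p.name == name:
                return p
        raise KeyError(name)


def _chinese_style_holidays(years) -> frozenset[dt.date]:
    """Fixed public-holiday offsets each year: Jan 1-3, May 1-3, Oct 1-7."""
    out = set()
    for y in years:
        out.update(dt.date(y, 1, d) for d in (1, 2, 3))
        out.update(dt.date(y, 5, d) for d in (1, 2, 3))
        out.update(dt.date(y, 10, d) for d in range(1, 8))
    return frozenset(out)


def default_config(seed: int = 0, n_days: int = 2557) -> SimulationConfig:
    """The study conditions: 2008-01-01 onward, five pollutants, known truths.

    Marginals are chosen to resemble a subtropical coastal city's monitoring
    network (winter-peaking pollution, summer-peaking temperature): SO2 ~12,
    NO2 ~46, PM10 ~56, CO ~1.2, O3 ~53 ug/m3 on average.  SO2/NO2/PM10 carry
    J-shaped truths with thresholds near their 75th percentiles; O3 a V shape
    around its median; CO is a null pollutant.  Daily counts average ~25 with
    dispersion 2.5, giving a marginal SD near 10.
    """
    start = dt.date(2008, 1, 1)
    w14 = decaying_weights(14)
    pollutants = (
        PollutantSpec(
            "so2",
            SeasonalSpec(12.0, 3.5, 0.75, 2.6, peak_day=15, shared_factor_loading=3.8),
            EffectSurfaceSpec("J", threshold_high=14.5, slope_high=0.02, lag_weights=w14),
        ),
        PollutantSpec(
            "no2",
            SeasonalSpec(46.0, 10.0, 0.75, 7.5, peak_day=15, shared_factor_loading=11.0),
            EffectSurfaceSpec("J", threshold_high=54.0, slope_high=0.006, lag_weights=w14),
        ),
        PollutantSpec(
            "pm10",
            SeasonalSpec(56.0, 16.0, 0.75, 11.0, peak_day=15, shared_factor_loading=16.0),
            EffectSurfaceSpec("J", threshold_high=75.0, slope_high=0.004, lag_weights=w14),
        ),
        PollutantSpec(
            "co",
            SeasonalSpec(1.2, 0.22, 0.75, 0.18, peak_day=15, shared_factor_loading=0.2),
            EffectSurfaceSpec("null"),
        ),
        PollutantSpec(
            "o3",
            SeasonalSpec(53.0, 10.0, 0.7, 12.0, peak_day=274, shared_factor_loading=3.0),
            EffectSurfaceSpec(
                "V",
                threshold_high=55.0,
                slope_high=0.004,
                threshold_low=45.0,
                slope_low=0.004,
                lag_weights=w14,
            ),
        ),
    )
    last_year = (start + dt.timedelta(days=n_days - 1)).year
    years = range(start.year, last_year + 1)
    return SimulationConfig(
        start_date=start,
        n_days=n_days,
        seed=seed,
        pollutants=pollutants,
        temp_spec=SeasonalSpec(23.0, 6.0, 0.8, 1.1, peak_day=196, shared_factor_loading=-0.9),
        rh_spec=SeasonalSpec(73.0, 7.0, 0.7, 5.0, peak_day=170, shared_factor_loading=-3.2),
        baseline_log_rate=float(np.log(25.0 / 10_500_000)),
        baseline_seasonal_amplitude=0.10,
        dispersion=2.5,
        population_by_year={y: 10_500_000 for y in years},
        holiday_effect=0.05,
        holiday_dates=_chinese_style_holidays(years),
    )


@dataclass
class SimulatedStudy:
    """Generated series plus the exact pre-noise mean for oracle checks."""

    series: pd.DataFrame
    true_mu: np.ndarray
    true_log_rr: np.ndarray  # summed pollutant surface contribution per day
    config: SimulationConfig

    @property
    def exposure_history(self) -> pd.DataFrame:
        """Exposures including the burn-in rows (index -maxlag .. n_days-1)."""
        return self._history

    _history: pd.DataFrame = None  # set by generate_series


def _simulate_seasonal(
    spec: SeasonalSpec, doy: np.ndarray, factor: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    n = doy.size
    base = spec.mean + spec.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - spec.peak_day) / DAYS_PER_YEAR
    )
    eps = np.empty(n)
    innov = rng.normal(0.0, spec.noise_sd, size=n)
    # stationary start
    eps[0] = innov[0] / np.sqrt(1 - spec.ar_coefficient**2)
    for t in range(1, n):
        eps[t] = spec.ar_coefficient * eps[t - 1] + innov[t]
    return base + spec.shared_factor_loading * factor + eps


def generate_series(config: SimulationConfig) -> SimulatedStudy:
    """Simulate the daily analysis table; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    burn = config.maxlag
    n_total = config.n_days + burn

    dates = pd.date_range(
        config.start_date - dt.timedelta(days=burn), periods=n_total, freq="D"
    )
    doy = dates.dayofyear.to_numpy(dtype=float)

    # latent daily factor shared across pollutants (induces cross-correlation)
    z = np.empty(n_total)
    innov = rng.normal(size=n_total)
    z[0] = innov[0] / np.sqrt(1 - config.factor_ar**2)
    for t in range(1, n_total):
        z[t] = config.factor_ar * z[t - 1] + innov[t]
    z = (z - z.mean()) / z.std()

    exposures = {}
    for p in config.pollutants:
        exposures[p.name] = np.maximum(
            _simulate_seasonal(p.series, doy, z, rng), EXPOSURE_FLOOR
        )
    temp = _simulate_seasonal(config.temp_spec, doy, z, rng)
    rh = np.clip(_simulate_seasonal(config.rh_spec, doy, z, rng), 0.0, 100.0)

    # true linear predictor on output days (burn-in supplies full lag history)
    out = slice(burn, n_total)
    log_rr = np.zeros(config.n_days)
    for p in config.pollutants:
        eff = p.effect
        if eff.shape == "null":
            continue
        fx = eff.f(exposures[p.name])
        for lag, w in enumerate(eff.lag_weights):
            log_rr += w * fx[burn - lag : n_total - lag]

    out_dates = dates[out]
    holiday = np.array(
        [d.date() in config.holiday_dates for d in out_dates], dtype=int
    )
    years = out_dates.year.to_numpy()
    population = np.array([config.population_by_year[y] for y in years])
    seasonal_baseline = config.baseline_seasonal_amplitude * np.cos(
        2 * np.pi * (doy[out] - 15.0) / DAYS_PER_YEAR
    )
    lp = (
        config.baseline_log_rate
        + seasonal_baseline
        + log_rr
        + config.holiday_effect * holiday
    )
    mu = population * np.exp(lp)

    if config.dispersion == 1.0:
        total = rng.poisson(mu)
    else:
        size = mu / (config.dispersion - 1.0)  # var = mu + mu^2/size = phi*mu
        total = rng.negative_binomial(size, size / (size + mu))
    male = rng.binomial(total, config.male_prob)
    elderly = rng.binomial(total, config.elderly_prob)

    series = pd.DataFrame(
        {
            "date": out_dates.date,
            "total": total,
            "male": male,
            "female": total - male,
            "elderly": elderly,
            "adult": total - elderly,
            **{name: exposures[name][out] for name in exposures},
            "temperature": temp[out],
            "relative_humidity": rh[out],
            "holiday": holiday,
            "population": population,
        }
    )
    history = pd.DataFrame(
        {name: exposures[name] for name in exposures},
        index=np.arange(-burn, config.n_days),
    )
    study = SimulatedStudy(
        series=series, true_mu=mu, true_log_rr=log_rr, config=config
    )
    study._history = history
    return study


def true_cumulative_log_rr(
    config: SimulationConfig,
    pollutant: str,
    at: float,
    ref: float,
    window: tuple[int, int],
) -> float:
    """Exact cumulative log-RR of ``at`` vs ``ref`` over lags l0..l1.

    Returns sum_{l=l0..l1} [f(at) - f(ref)] * w(l) from the planted surface.
    """
    eff = config.pollutant(pollutant).effect
    if eff.shape == "null":
        raise ValueError(f"pollutant {pollutant!r} has a null effect surface")
    l0, l1 = window
    if not 0 <= l0 <= l1 <= eff.maxlag:
        raise ValueError(f"window {window} outside 0..{eff.maxlag}")
    wsum = float(np.sum(eff.lag_weights[l0 : l1 + 1]))
    return float((eff.f(at) - eff.f(ref)) * wsum)


def write_series_csv(series: pd.DataFrame, path) -> None:
    series.to_csv(path, index=False, date_format="%Y-%m-%d")


def read_series_csv(path) -> pd.DataFrame:
    """Read and validate a daily series CSV (see :func:`validate_series`)."""
    df = pd.read_csv(path, parse_dates=["date"])
    df["date"] = df["date"].dt.date
    validate_series(df)
    return df


def validate_series(series: pd.DataFrame, pollutants=None) -> None:
    """Schema check: required columns, consecutive dates, physical ranges."""
    required = ["date", *GROUP_COLUMNS, "temperature", "relative_humidity",
                "holiday", "population"]
    if pollutants is not None:
        required += list(pollutants)
    missing = [c for c in required if c not in series.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    dates = pd.to_datetime(series["date"])
    gaps = dates.diff().dt.days.iloc[1:]
    if not (gaps == 1).all():
        bad = dates.iloc[1:][gaps != 1].iloc[0].date()
        raise ValueError(f"dates must be strictly consecutive (gap before {bad})")
    if (series[list(GROUP_COLUMNS)] < 0).any().any():
        raise ValueError("counts must be nonnegative")
    rh = series["relative_humidity"]
    if (rh < 0).any() or (rh > 100).any():
        raise ValueError("relative humidity must lie in [0, 100]")
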