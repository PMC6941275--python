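"""The synthetic-data generator and its ground-truth arithmetic."""

import dataclasses
import datetime as dt
import io

import numpy as np
import pytest

import lagrisk as lr
from lagrisk import simulate
from lagrisk.simulate import (
    EffectSurfaceSpec,
    default_config,
    generate_series,
    true_cumulative_log_rr,
    uniform_weights,
    write_series_csv,
)

from conftest import null_poisson_config, recovery_config


def brute_force_mu(study):
    """Recompute mu_t row by row with an independent loop over the stored
    exposure history (the oracle for the generator's mean structure)."""
    cfg = study.config
    hist = study.exposure_history
    series = study.series
    mu = np.empty(len(series))
    for t in range(len(series)):
        lp = cfg.baseline_log_rate
        doy = series["date"].iloc[t].timetuple().tm_yday
        lp += cfg.baseline_seasonal_amplitude * np.cos(
            2 * np.pi * (doy - 15.0) / 365.25
        )
        for p in cfg.pollutants:
            eff = p.effect
            if eff.shape == "null":
                continue
            for lag, w in enumerate(eff.lag_weights):
                lp += w * float(eff.f(hist.loc[t - lag, p.name]))
        if series["date"].iloc[t] in cfg.holiday_dates:
            lp += cfg.holiday_effect
        mu[t] = cfg.population_by_year[series["date"].iloc[t].year] * np.exp(lp)
    return mu


class TestGenerateSeries:
    def test_determinism(self):
        cfg = default_config(seed=42, n_days=400)
        a, b = generate_series(cfg), generate_series(cfg)
        for buf_a, buf_b in [(io.StringIO(), io.StringIO())]:
            write_series_csv(a.series, buf_a)
            write_series_csv(b.series, buf_b)
            assert buf_a.getvalue() == buf_b.getvalue()
        assert np.array_equal(a.true_mu, b.true_mu)

    def test_schema_invariants(self, default_study):
        s = default_study.series
        assert len(s) == 2557
        assert (s["male"] + s["female"] == s["total"]).all()
        assert (s["elderly"] + s["adult"] == s["total"]).all()
        assert (s[["so2", "no2", "pm10", "co", "o3"]] > 0).all().all()
        assert s["relative_humidity"].between(0, 100).all()
        gaps = np.diff([d.toordinal() for d in s["date"]])
        assert (gaps == 1).all()

    def test_null_poisson_mean(self):
        """All-null, dispersion-1 config: counts are plain Poisson around
        Population*exp(baseline + seasonal); the sample mean is within 3 SE
        of the analytic mean of mu."""
        study = generate_series(null_poisson_config(5))
        mu = study.true_mu
        se = np.sqrt(mu.sum()) / len(mu)
        assert abs(study.series["total"].mean() - mu.mean()) < 3 * se
        assert np.allclose(study.true_log_rr, 0.0)

    def test_mu_matches_brute_force(self):
        study = generate_series(default_config(seed=9, n_days=400))
        ref = brute_force_mu(study)
        assert np.abs(study.true_mu / ref - 1).max() < 1e-10

    def test_high_exposure_days_have_higher_means(self):
        """J-shaped truth: mean pre-noise rate after high-exposure episodes
        exceeds the mean after low-exposure episodes."""
        study = generate_series(recovery_config(3))
        s = study.series
        x = s["so2"].to_numpy()
        ma = np.convolve(x, np.ones(15) / 15, mode="full")[14 : len(x)]
        mu = study.true_mu[14:]
        hi, lo = ma > np.quantile(ma, 0.8), ma < np.quantile(ma, 0.2)
        assert mu[hi].mean() > mu[lo].mean()

    def test_dispersion_one_pearson_near_unity(self):
        study = generate_series(null_poisson_config(17))
        y, mu = study.series["total"].to_numpy(), study.true_mu
        pearson = np.sum((y - mu) ** 2 / mu) / len(y)
        assert 0.9 < pearson < 1.1

    def test_shared_loading_drives_correlation(self):
        """Spearman correlation between two pollutants is positive and
        increases with the product of their shared-factor loadings."""
        def corr_at(loading, seed):
            cfg = default_config(seed=seed, n_days=400)
            pols = tuple(
                dataclasses.replace(
                    p, series=dataclasses.replace(p.series, shared_factor_loading=loading)
                )
                for p in cfg.pollutants
                if p.name in ("so2", "no2")
            )
            cfg = dataclasses.replace(cfg, pollutants=pols)
            s = generate_series(cfg).series
            from scipy.stats import spearmanr
            return spearmanr(s["so2"], s["no2"]).statistic

        means = []
        for loading in (1.0, 3.0, 6.0):
            means.append(np.mean([corr_at(loading, seed) for seed in range(10)]))
        assert means[0] > 0
        assert means[0] < means[1] < means[2]

    def test_validation_errors(self):
        cfg = default_config(seed=0)
        with pytest.raises(ValueError, match="366"):
            dataclasses.replace(cfg, n_days=100)
        with pytest.raises(ValueError, match="population"):
            dataclasses.replace(cfg, population_by_year={2008: 1_000_000})


class TestTrueCumulativeLogRR:
    @pytest.fixture
    def config(self):
        eff = EffectSurfaceSpec(
            "J", threshold_high=50.0, slope_high=0.01, lag_weights=uniform_weights(14)
        )
        cfg = default_config(seed=0)
        pols = tuple(
            dataclasses.replace(p, effect=eff) if p.name == "so2" else p
            for p in cfg.pollutants
        )
        return dataclasses.replace(cfg, pollutants=pols)

    def test_identity_at_equal_exposures(self, config):
        for window in [(0, 0), (0, 7), (0, 14)]:
            assert true_cumulative_log_rr(config, "so2", 60.0, 60.0, window) == 0.0

    def test_below_threshold_is_zero(self, config):
        assert true_cumulative_log_rr(config, "so2", 45.0, 30.0, (0, 14)) == 0.0

    def test_hand_sum(self, config):
        """theta=0.01, x0=50, at=100, ref=40, uniform weights over 0..14:
        the 15 weighted terms sum to 0.01*(100-50)*1 = 0.5."""
        got = true_cumulative_log_rr(config, "so2", 100.0, 40.0, (0, 14))
        assert got == pytest.approx(0.5, abs=1e-12)
        # partial window scales by the weight mass it covers
        got = true_cumulative_log_rr(config, "so2", 100.0, 40.0, (0, 4))
        assert got == pytest.approx(0.5 * 5 / 15, abs=1e-12)

    def test_window_and_null_rejection(self, config):
        with pytest.raises(ValueError, match="window"):
            true_cumulative_log_rr(config, "so2", 60.0, 40.0, (0, 15))
        with pytest.raises(ValueError, match="null"):
            true_cumulative_log_rr(config, "co", 1.0, 0.5, (0, 14))


class TestSeriesIO:
    def test_round_trip(self, tmp_path, short_study):
        path = tmp_path / "series.csv"
        write_series_csv(short_study.series, path)
        back = simulate.read_series_csv(path)
        assert back.shape == short_study.series.shape
        assert (back["total"] == short_study.series["total"]).all()

    def test_gap_rejected(self, tmp_path, short_study):
        broken = short_study.series.drop(index=5)
        path = tmp_path / "gap.csv"
        write_series_csv(broken, path)
        with pytest.raises(ValueError, match="consecutive"):
            simulate.read_series_csv(path)

    def test_missing_column_named(self, short_study):
        with pytest.raises(ValueError, match="pm10"):
            simulate.validate_series(
                short_study.series.drop(columns=["pm10"]), pollutants=["pm10"]
            )
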