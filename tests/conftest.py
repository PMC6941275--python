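import dataclasses

import numpy as np
import pandas as pd
import pytest

import lagrisk as lr
from lagrisk.fitting import DesignMatrix
from lagrisk.simulate import EffectSurfaceSpec, default_config, uniform_weights


def null_poisson_config(seed: int) -> lr.SimulationConfig:
    """Study conditions with every effect surface null and dispersion 1."""
    cfg = default_config(seed=seed)
    pols = tuple(
        dataclasses.replace(p, effect=EffectSurfaceSpec("null"))
        for p in cfg.pollutants
    )
    return dataclasses.replace(cfg, pollutants=pols, dispersion=1.0)


def recovery_config(seed: int) -> lr.SimulationConfig:
    """A J-shaped truth planted in SO2 only (threshold near its 75th
    percentile, slope 0.035/unit, uniform lag weights over 0..14), all other
    pollutants null, so the single-pollutant estimand equals the planted
    cumulative log-RR (~0.4, RR ~1.5, at the 99th-vs-median contrast)."""
    cfg = default_config(seed=seed)
    eff = EffectSurfaceSpec(
        "J", threshold_high=14.5, slope_high=0.035, lag_weights=uniform_weights(14)
    )
    pols = tuple(
        dataclasses.replace(p, effect=eff)
        if p.name == "so2"
        else dataclasses.replace(p, effect=EffectSurfaceSpec("null"))
        for p in cfg.pollutants
    )
    return dataclasses.replace(cfg, pollutants=pols)


@pytest.fixture(scope="session")
def default_study():
    return lr.generate_series(default_config(seed=7))


@pytest.fixture(scope="session")
def short_study():
    """A two-year series for fast fitting tests."""
    return lr.generate_series(default_config(seed=11, n_days=731))


@pytest.fixture
def tiny_design():
    """Six days, two strata, one binary exposure column; small enough for a
    brute-force likelihood oracle."""
    return DesignMatrix(
        y=np.array([3.0, 5.0, 2.0, 8.0, 4.0, 6.0]),
        offset=np.zeros(6),
        X=np.column_stack([np.ones(6), [0.0, 1.0, 0.0, 1.0, 0.0, 1.0]]),
        columns=["intercept", "x:v1:l1"],
        strata=np.array([0, 0, 0, 1, 1, 1]),
        stratum_labels=["2008-01", "2008-02"],
        mask=np.ones(6, dtype=bool),
        subgroup="total",
    )


def make_series(n: int, seed: int = 0, start: str = "2008-01-01") -> pd.DataFrame:
    """Minimal hand-built daily series (no generator) for design tests."""
    rng = np.random.default_rng(seed)
    total = rng.poisson(20, n)
    male = rng.binomial(total, 0.6)
    elderly = rng.binomial(total, 0.5)
    return pd.DataFrame(
        {
            "date": pd.date_range(start, periods=n, freq="D").date,
            "total": total,
            "male": male,
            "female": total - male,
            "elderly": elderly,
            "adult": total - elderly,
            "so2": rng.uniform(3, 40, n),
            "temperature": rng.uniform(10, 30, n),
            "relative_humidity": rng.uniform(40, 95, n),
            "holiday": (rng.uniform(size=n) < 0.05).astype(int),
            "population": np.full(n, 1_000_000),
        }
    )
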