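"""Study orchestration: descriptives, model selection, subgroups, sensitivity.

The full analysis of a daily series runs as: describe -> Spearman
correlations -> single-pollutant screen -> multi-pollutant selection
(collinearity rule + Q-AIC) -> per-group fits and extreme-influence tables ->
sensitivity scan over spline df and maximal lag.  Every stage is also
callable on its own.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import simulate
from .basis import CrossBasis, build_cross_basis
from .effects import DEFAULT_WINDOWS, extreme_influence_table, overall_curve
from .fitting import FitResult, build_design, fit_quasipoisson, qaic

__all__ = [
    "AnalysisSettings",
    "ModelPlan",
    "describe_series",
    "spearman_matrix",
    "build_crossbases",
    "fit_model",
    "single_pollutant_screen",
    "select_models",
    "stratified_analysis",
    "sensitivity_scan",
    "run_study",
]

logger = logging.getLogger("lagrisk")

POLLUTANTS = ("so2", "no2", "pm10", "co", "o3")
MET_COLUMNS = ("temperature", "relative_humidity")
SUBGROUPS = ("total", "male", "female", "elderly", "adult")

PERCENTILE_PROBS = (1, 5, 10, 25, 50, 75, 90, 95, 99)


@dataclass(frozen=True)
class AnalysisSettings:
    """Model hyperparameters: spline df and maximal lags.

    Defaults follow the primary analysis: natural cubic splines with 3 df in
    both the exposure and lag dimensions, maximal lag 14 days for pollutants
    and 3 days for meteorology.
    """

    df_var: int = 3
    df_lag: int = 3
    maxlag: int = 14
    met_df_var: int = 3
    met_df_lag: int = 3
    met_maxlag: int = 3
    windows: tuple = DEFAULT_WINDOWS
    day_of_week: bool = False

    def clipped_windows(self) -> tuple:
        out = []
        for l0, l1 in self.windows:
            if l0 <= self.maxlag:
                out.append((l0, min(l1, self.maxlag)))
        return tuple(dict.fromkeys(out))


def describe_series(series: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Mean, SD, min, percentiles and IQR per variable (one row each).

    Percentiles use linear interpolation between order statistics;
    IQR = P75 - P25.
    """
    if columns is None:
        columns = [c for c in series.columns
                   if c not in ("date", "holiday", "population")]
    rows = {}
    for col in columns:
        v = pd.to_numeric(series[col], errors="raise").to_numpy(dtype=float)
        if v.size == 0:
            raise ValueError(f"empty column {col!r}")
        pct = np.quantile(v, [p / 100 for p in PERCENTILE_PROBS])
        row = {"mean": v.mean(), "sd": v.std(ddof=1), "min": v.min()}
        row.update({f"p{p}": x for p, x in zip(PERCENTILE_PROBS, pct)})
        row["max"] = v.max()
        row["iqr"] = row["p75"] - row["p25"]
        rows[col] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def spearman_matrix(series: pd.DataFrame, variables) -> pd.DataFrame:
    """Spearman rank correlations (average ranks for ties); symmetric,
    diagonal exactly 1; constant columns yield NaN entries (flagged)."""
    data = series[list(variables)].to_numpy(dtype=float)
    if data.shape[0] < 3:
        raise ValueError("need at least 3 rows")
    rho = stats.spearmanr(data).statistic
    if np.ndim(rho) == 0:  # scipy collapses the two-variable case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    for j, v in enumerate(variables):
        if np.nanstd(data[:, j]) == 0:
            logger.warning("constant column %s: correlation undefined", v)
    np.fill_diagonal(rho, 1.0)
    rho = (rho + rho.T) / 2
    return pd.DataFrame(rho, index=list(variables), columns=list(variables))


def build_crossbases(
    series: pd.DataFrame, pollutants, settings: AnalysisSettings
) -> dict[str, CrossBasis]:
    """Cross-bases for the named pollutants plus the meteorology terms."""
    cbs = {}
    for name in pollutants:
        if name not in series.columns:
            raise ValueError(f"missing pollutant column {name!r}")
        cbs[name] = build_cross_basis(
            series[name].to_numpy(dtype=float), name=name,
            df_var=settings.df_var, df_lag=settings.df_lag,
            maxlag=settings.maxlag,
        )
    for name in MET_COLUMNS:
        cbs[name] = build_cross_basis(
            series[name].to_numpy(dtype=float), name=name,
            df_var=settings.met_df_var, df_lag=settings.met_df_lag,
            maxlag=settings.met_maxlag,
        )
    return cbs


def fit_model(
    series: pd.DataFrame,
    pollutants,
    settings: AnalysisSettings = AnalysisSettings(),
    subgroup: str = "total",
    cbs: dict[str, CrossBasis] | None = None,
    method: str = "indicators",
) -> tuple[FitResult, dict[str, CrossBasis]]:
    """Fit one (single- or multi-pollutant) model for one subgroup."""
    if cbs is None:
        cbs = build_crossbases(series, pollutants, settings)
    design = build_design(
        series, list(cbs.values()), subgroup=subgroup,
        day_of_week=settings.day_of_week,
    )
    return fit_quasipoisson(design, method=method), cbs


def single_pollutant_screen(
    series: pd.DataFrame,
    pollutants=POLLUTANTS,
    settings: AnalysisSettings = AnalysisSettings(),
) -> pd.DataFrame:
    """Single-pollutant models for the total group; a pollutant is flagged
    significant when any extreme-contrast cell's CI excludes 1 at any stated
    window (the criterion used to drop pollutants from further modelling)."""
    rows = []
    for name in pollutants:
        fit, cbs = fit_model(series, [name], settings)
        mask = np.arange(len(series)) >= settings.maxlag
        table = extreme_influence_table(
            {"total": fit}, {name: cbs[name]}, series,
            windows=settings.clipped_windows(), mask=mask,
        )
        rows.append(
            {
                "pollutant": name,
                "significant": bool(table["significant"].any()),
                "n_significant_cells": int(table["significant"].sum()),
                "qaic": fit.qaic,
                "dispersion": fit.dispersion,
            }
        )
        logger.info("screen %-6s significant=%s", name, rows[-1]["significant"])
    return pd.DataFrame(rows).set_index("pollutant")


@dataclass
class ModelPlan:
    """Candidate pollutant models after the screen and collinearity rule."""

    candidates: list[tuple[str, ...]]
    excluded_pairs: list[dict]
    dropped_pollutants: list[str]
    qaic_by_candidate: dict[tuple[str, ...], float] = field(default_factory=dict)
    reporting_model: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"candidate": "+".join(c), "qaic": self.qaic_by_candidate.get(c, np.nan)}
            for c in self.candidates
        ]
        return pd.DataFrame(rows)


def select_models(
    corr: pd.DataFrame,
    screen: pd.DataFrame,
    threshold: float = 0.60,
) -> ModelPlan:
    """Apply the screen and the collinearity rule to enumerate candidates.

    Pollutants without a significant single-model association are dropped;
    pairs with Spearman r > ``threshold`` are excluded from joint models;
    remaining singles and pairs become candidates.
    """
    if not np.allclose(corr.to_numpy(), corr.to_numpy().T, equal_nan=True):
        raise ValueError("correlation matrix must be symmetric")
    kept = [p for p in screen.index if bool(screen.loc[p, "significant"])]
    dropped = [p for p in screen.index if p not in kept]
    candidates: list[tuple[str, ...]] = [(p,) for p in kept]
    excluded = []
    for i, a in enumerate(kept):
        for b in kept[i + 1:]:
            r = float(corr.loc[a, b])
            if abs(r) > threshold:
                excluded.append({"pair": (a, b), "r": r, "reason": f"|r|>{threshold}"})
            else:
                candidates.append((a, b))
    if not kept:
        logger.warning("no pollutant passed the single-model screen")
    return ModelPlan(candidates=candidates, excluded_pairs=excluded,
                     dropped_pollutants=dropped)


def rank_models(
    plan: ModelPlan,
    series: pd.DataFrame,
    settings: AnalysisSettings = AnalysisSettings(),
) -> ModelPlan:
    """Fit every candidate and rank by Q-AIC; pick each pollutant's
    reporting model (its lowest-Q-AIC candidate, preferring joint models
    so confounding by co-pollutants is adjusted when permissible).

    Q-AIC is computed with each candidate's own Pearson dispersion; when
    comparing candidates for one pollutant the largest (joint) model's
    dispersion is applied to all, so all share one scale.
    """
    fits = {}
    for cand in plan.candidates:
        fit, _ = fit_model(series, list(cand), settings)
        fits[cand] = fit
        plan.qaic_by_candidate[cand] = fit.qaic
    for cand in plan.candidates:
        if len(cand) == 1:
            p = cand[0]
            options = [c for c in plan.candidates if p in c]
            largest = max(options, key=len)
            phi = fits[largest].dispersion
            best = min(options, key=lambda c: qaic(fits[c], dispersion=phi))
            plan.reporting_model[p] = best
    return plan


def stratified_analysis(
    series: pd.DataFrame,
    pollutants,
    settings: AnalysisSettings = AnalysisSettings(),
    groups=SUBGROUPS,
) -> tuple[pd.DataFrame, dict[str, FitResult], dict[str, CrossBasis]]:
    """The identical model refitted with each subgroup's counts as response.

    Returns the combined extreme-influence table (Tables-4/5 layout), the
    per-group fits and the shared cross-bases.
    """
    for g in groups:
        if g not in series.columns:
            raise ValueError(f"missing subgroup count column {g!r}")
        if int(series[g].sum()) == 0:
            raise ValueError(f"subgroup {g!r} has all-zero counts")
    cbs = build_crossbases(series, pollutants, settings)
    fits = {}
    for g in groups:
        fits[g], _ = fit_model(series, pollutants, settings, subgroup=g, cbs=cbs)
    mask = np.arange(len(series)) >= settings.maxlag
    table = extreme_influence_table(
        fits, {p: cbs[p] for p in pollutants}, series,
        windows=settings.clipped_windows(), mask=mask,
    )
    return table, fits, cbs


def sensitivity_scan(
    series: pd.DataFrame,
    pollutant: str,
    base: AnalysisSettings = AnalysisSettings(),
    df_var_grid=(2, 3, 4, 5, 6),
    df_lag_grid=(2, 3, 4, 5, 6),
    maxlag_grid=tuple(range(12, 22)),
    window: tuple[int, int] = (0, 12),
) -> pd.DataFrame:
    """Refit the single-pollutant model across df and maxlag grids.

    Reports the cumulative 99th-vs-median log-RR at each grid point and its
    absolute change from the base settings; singular fits are logged and
    skipped.  The base grid point reproduces the main analysis exactly.
    """
    def one(settings: AnalysisSettings) -> dict | None:
        try:
            fit, cbs = fit_model(series, [pollutant], settings)
        except (RuntimeError, np.linalg.LinAlgError) as exc:
            logger.warning("skipping %s: %s", settings, exc)
            return None
        cb = cbs[pollutant]
        mask = np.arange(len(series)) >= settings.maxlag
        v = series[pollutant].to_numpy(dtype=float)[mask]
        med, hi = np.quantile(v, [0.50, 0.99])
        w = (window[0], min(window[1], settings.maxlag))
        from .effects import cumulative_rr
        est = cumulative_rr(fit, cb, hi, med, w)
        return {
            "df_var": settings.df_var, "df_lag": settings.df_lag,
            "maxlag": settings.maxlag, "window": f"lag{w[0]}-{w[1]}",
            "log_rr": est.log_rr, "rr": est.rr, "lo": est.lo, "hi": est.hi,
            "se": est.se, "qaic": fit.qaic,
        }

    rows = []
    base_row = one(base)
    if base_row is None:
        raise RuntimeError("base settings failed to fit")
    base_row["scan"] = "base"
    rows.append(base_row)
    for dv in df_var_grid:
        for dl in df_lag_grid:
            if (dv, dl) == (base.df_var, base.df_lag):
                continue
            r = one(replace(base, df_var=dv, df_lag=dl))
            if r:
                r["scan"] = "df"
                rows.append(r)
    for ml in maxlag_grid:
        if ml == base.maxlag:
            continue
        r = one(replace(base, maxlag=ml))
        if r:
            r["scan"] = "maxlag"
            rows.append(r)
    out = pd.DataFrame(rows)
    out["abs_change_vs_base"] = (out["log_rr"] - base_row["log_rr"]).abs()
    return out


def run_study(config: dict, out_dir) -> dict:
    """Execute the full study from a config mapping; write CSVs to out_dir.

    Config keys: ``simulate`` (mapping passed to the generator: seed, n_days)
    or ``input_csv``; ``pollutants``; ``settings`` (AnalysisSettings fields);
    ``subgroups``; ``sensitivity`` (bool or mapping with pollutant/grids).
    Deterministic given the config; a run log records every stage.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    artifacts = {}
    try:
        pollutants = tuple(config.get("pollutants", POLLUTANTS))
        settings = AnalysisSettings(**config.get("settings", {}))

        # stage 1: data
        if "input_csv" in config:
            series = simulate.read_series_csv(config["input_csv"])
            simulate.validate_series(series, pollutants=pollutants)
        else:
            sim_cfg = dict(config.get("simulate", {}))
            cfg = simulate.default_config(
                seed=int(sim_cfg.get("seed", 0)),
                n_days=int(sim_cfg.get("n_days", 2557)),
            )
            series = simulate.generate_series(cfg).series
            simulate.write_series_csv(series, out / "series.csv")
        logger.info("stage data: %d days", len(series))

        # stage 2-3: descriptives and correlations
        desc = describe_series(series)
        desc.round(4).to_csv(out / "descriptives.csv")
        corr = spearman_matrix(series, list(pollutants) + list(MET_COLUMNS))
        corr.round(4).to_csv(out / "spearman.csv")
        artifacts["descriptives"], artifacts["spearman"] = desc, corr

        # stage 4-5: screen and selection
        screen = single_pollutant_screen(series, pollutants, settings)
        screen.to_csv(out / "screen.csv")
        plan = select_models(corr.loc[list(pollutants), list(pollutants)], screen)
        plan = rank_models(plan, series, settings)
        plan.to_frame().round(2).to_csv(out / "model_plan.csv", index=False)
        artifacts["screen"], artifacts["plan"] = screen, plan

        # stage 6-7: effects for reporting models, all subgroups
        subgroups = tuple(config.get("subgroups", SUBGROUPS))
        tables = []
        for p, cand in plan.reporting_model.items():
            table, fits, cbs = stratified_analysis(
                series, list(cand), settings, groups=subgroups
            )
            table = table[table["pollutant"] == p].copy()
            table["model"] = "+".join(cand)
            tables.append(table)
            grid = np.linspace(*cbs[p].spec.var_spec.boundary, 50)
            med = float(np.quantile(
                series[p].to_numpy(dtype=float)[settings.maxlag:], 0.50))
            curve = overall_curve(fits["total"], cbs[p], grid, med, (0, settings.maxlag))
            curve.round(6).to_csv(out / f"curve_{p}.csv", index=False)
        if tables:
            influence = pd.concat(tables, ignore_index=True)
            influence.round(6).to_csv(out / "extreme_influence.csv", index=False)
            artifacts["influence"] = influence

        # stage 8: sensitivity
        sens_cfg = config.get("sensitivity", False)
        if sens_cfg:
            sens_cfg = sens_cfg if isinstance(sens_cfg, dict) else {}
            target = sens_cfg.get(
                "pollutant",
                next(iter(plan.reporting_model), pollutants[0]),
            )
            sens = sensitivity_scan(
                series, target, settings,
                df_var_grid=tuple(sens_cfg.get("df_var_grid", (2, 3, 4, 5, 6))),
                df_lag_grid=tuple(sens_cfg.get("df_lag_grid", (2, 3, 4, 5, 6))),
                maxlag_grid=tuple(sens_cfg.get("maxlag_grid", range(12, 22))),
            )
            sens.round(6).to_csv(out / "sensitivity.csv", index=False)
            artifacts["sensitivity"] = sens

        summary = {
            "n_days": int(len(series)),
            "pollutants": list(pollutants),
            "dropped_pollutants": plan.dropped_pollutants,
            "excluded_pairs": [
                {"pair": list(e["pair"]), "r": e["r"]} for e in plan.excluded_pairs
            ],
            "reporting_models": {
                p: "+".join(c) for p, c in plan.reporting_model.items()
            },
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        artifacts["summary"] = summary
        return artifacts
    except Exception:
        logger.exception("study run aborted")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
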