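"""Relative-risk estimation from a fitted cross-basis block.

Every quantity here is a linear contrast of the cross-basis coefficients.
For exposure value ``at`` versus reference ``ref`` at single lag ``l`` the
contrast vector is c_(j,k) = [R_j(at) - R_j(ref)] * C_k(l); cumulative
contrasts over a lag window sum the single-lag contrasts.  log-RR = c'beta,
SE = sqrt(c'Vc) (delta method on the log scale), and the 95% CI is
exp(log_rr +/- 1.959964 * SE).

No extrapolation: ``at`` and ``ref`` must lie inside the exposure basis
boundary (the observed concentration range).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import CrossBasis
from .fitting import FitResult

__all__ = [
    "Z95",
    "EffectEstimate",
    "lag_specific_rr",
    "cumulative_rr",
    "overall_curve",
    "extreme_influence_table",
    "DEFAULT_WINDOWS",
]

Z95 = 1.959964  # exact two-sided 95% normal quantile
DEFAULT_WINDOWS = ((0, 1), (0, 6), (0, 8), (0, 10), (0, 12), (0, 13), (0, 14))


@dataclass(frozen=True)
class EffectEstimate:
    """A relative risk with 95% CI at a stated contrast and lag window."""

    term: str
    at: float
    ref: float
    window: tuple[int, int]
    log_rr: float
    se: float

    @property
    def rr(self) -> float:
        return float(np.exp(self.log_rr))

    @property
    def lo(self) -> float:
        return float(np.exp(self.log_rr - Z95 * self.se))

    @property
    def hi(self) -> float:
        return float(np.exp(self.log_rr + Z95 * self.se))

    @property
    def significant(self) -> bool:
        """CI excludes RR = 1."""
        return self.lo > 1.0 or self.hi < 1.0


def _check_range(cb: CrossBasis, value: float, label: str) -> None:
    a, b = cb.spec.var_spec.boundary
    if not a <= value <= b:
        raise ValueError(
            f"{label}={value} outside the exposure range [{a:.6g}, {b:.6g}] "
            f"of {cb.name!r}; extrapolation is not supported"
        )


def _contrast(cb: CrossBasis, at: float, ref: float, lags) -> np.ndarray:
    """Summed contrast vector over the given lags, (j outer, k inner)."""
    _check_range(cb, at, "at")
    _check_range(cb, ref, "ref")
    dr = cb.var_basis(at) - cb.var_basis(ref)  # (df_var,)
    cmat = cb.lag_basis()  # (maxlag+1, df_lag)
    csum = cmat[list(lags)].sum(axis=0)  # (df_lag,)
    return np.outer(dr, csum).ravel()


def _estimate(fit: FitResult, cb: CrossBasis, c: np.ndarray, at, ref, window) -> EffectEstimate:
    beta, vcov, _ = fit.block(cb.name)
    log_rr = float(c @ beta)
    var = float(c @ vcov @ c)
    return EffectEstimate(
        term=cb.name, at=float(at), ref=float(ref), window=tuple(window),
        log_rr=log_rr, se=float(np.sqrt(max(var, 0.0))),
    )


def lag_specific_rr(
    fit: FitResult, cb: CrossBasis, at: float, ref: float, lag: int
) -> EffectEstimate:
    """RR of ``at`` vs ``ref`` at one single lag day."""
    if not 0 <= lag <= cb.maxlag:
        raise ValueError(f"lag {lag} outside 0..{cb.maxlag}")
    c = _contrast(cb, at, ref, [lag])
    return _estimate(fit, cb, c, at, ref, (lag, lag))


def cumulative_rr(
    fit: FitResult, cb: CrossBasis, at: float, ref: float, window: tuple[int, int]
) -> EffectEstimate:
    """Cumulative RR of ``at`` vs ``ref`` over lags l0..l1."""
    l0, l1 = window
    if not 0 <= l0 <= l1 <= cb.maxlag:
        raise ValueError(f"window {window} outside 0..{cb.maxlag}")
    c = _contrast(cb, at, ref, range(l0, l1 + 1))
    return _estimate(fit, cb, c, at, ref, window)


def overall_curve(
    fit: FitResult,
    cb: CrossBasis,
    grid: np.ndarray,
    ref: float,
    window: tuple[int, int],
) -> pd.DataFrame:
    """Cumulative exposure-response curve over a grid of exposure values.

    Passes exactly through RR = 1 at the reference value.
    """
    rows = []
    for x in np.asarray(grid, dtype=float):
        est = cumulative_rr(fit, cb, x, ref, window)
        rows.append({"exposure": x, "rr": est.rr, "lo": est.lo, "hi": est.hi,
                     "log_rr": est.log_rr, "se": est.se})
    return pd.DataFrame(rows)


def exposure_percentiles(
    series_values: np.ndarray, probs=(1, 50, 99)
) -> dict[int, float]:
    """Percentiles of the analyzed exposure series (linear interpolation)."""
    v = np.asarray(series_values, dtype=float)
    if np.nanmax(v) == np.nanmin(v):
        raise ValueError("degenerate (constant) exposure series")
    return {int(p): float(np.nanquantile(v, p / 100)) for p in probs}


def extreme_influence_table(
    fits: dict[str, FitResult],
    cbs: dict[str, CrossBasis],
    series: pd.DataFrame,
    windows=DEFAULT_WINDOWS,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Cumulative RRs contrasting the 1st/99th exposure percentiles vs median.

    ``fits`` maps population-group label -> FitResult (all sharing the
    cross-bases in ``cbs``); one tidy row per (pollutant, group, block,
    window) with the percentile values used recorded alongside.
    Percentiles are computed from the analyzed (post-mask) series.
    """
    rows = []
    for name, cb in cbs.items():
        values = series[name].to_numpy(dtype=float)
        if mask is not None:
            values = values[mask]
        pct = exposure_percentiles(values)
        for group, fit in fits.items():
            for block, at in (("extreme_low", pct[1]), ("extreme_high", pct[99])):
                for window in windows:
                    est = cumulative_rr(fit, cb, at, pct[50], window)
                    rows.append(
                        {
                            "pollutant": name,
                            "group": group,
                            "block": block,
                            "window": f"lag{window[0]}-{window[1]}",
                            "rr": est.rr,
                            "lo": est.lo,
                            "hi": est.hi,
                            "at": est.at,
                            "ref": est.ref,
                            "significant": est.significant,
                        }
                    )
    return pd.DataFrame(rows)
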