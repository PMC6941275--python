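"""Quasi-Poisson estimation with time-stratum fixed effects and offset.

The time-stratified case-crossover design is estimated as a Poisson
regression of the daily count on the cross-basis terms, a holiday indicator
and fixed effects for each (year, calendar month) stratum, with offset
log(population).  Overdispersion is handled quasi-likelihood style: the
dispersion phi is estimated from the Pearson statistic and scales the
coefficient covariance; Q-AIC = -2*loglik/phi + 2p ranks candidate models.

Two numerically distinct routes to the same estimate are provided:

* ``method="indicators"`` — explicit stratum dummy columns, fitted with
  statsmodels GLM (the reference route);
* ``method="absorb"`` — the conditional formulation: stratum effects are
  profiled out in closed form inside IRLS and the remaining covariates are
  within-stratum weighted-centered (Frisch-Waugh).  Identical non-stratum
  coefficients in exact arithmetic; the agreement of the two routes is the
  case-crossover/Poisson equivalence the design relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import gammaln

from .basis import CrossBasis

__all__ = ["DesignMatrix", "FitResult", "build_design", "fit_quasipoisson", "qaic"]


@dataclass
class DesignMatrix:
    """Response, offset and covariate blocks for one model.

    ``X`` holds intercept, cross-basis blocks, holiday (and optional
    day-of-week dummies); stratum membership is carried separately as integer
    codes so either fitting route can use it.  ``mask`` flags rows with
    complete lag history; only masked-in rows enter the fit.
    """

    y: np.ndarray
    offset: np.ndarray
    X: np.ndarray
    columns: list[str]
    strata: np.ndarray  # integer stratum code per row
    stratum_labels: list[str]
    mask: np.ndarray
    subgroup: str

    @property
    def n_used(self) -> int:
        return int(self.mask.sum())

    def with_indicators(self) -> tuple[np.ndarray, list[str]]:
        """Covariates plus stratum dummies (reference level dropped)."""
        n = self.y.size
        k = len(self.stratum_labels)
        dummies = np.zeros((n, k - 1))
        for j in range(1, k):
            dummies[self.strata == j, j - 1] = 1.0
        names = self.columns + [f"stratum[{s}]" for s in self.stratum_labels[1:]]
        return np.hstack([self.X, dummies]), names


def build_design(
    series: pd.DataFrame,
    crossbases: list[CrossBasis],
    subgroup: str = "total",
    day_of_week: bool = False,
) -> DesignMatrix:
    """Assemble the design for one subgroup's counts.

    Strata are (year, calendar month) of each date; the offset is
    log(population); rows within the longest maxlag of the series start are
    masked out (incomplete lag history).
    """
    if subgroup not in series.columns:
        raise ValueError(f"no count column {subgroup!r} in series")
    n = len(series)
    if n == 0:
        raise ValueError("empty series")
    y = series[subgroup].to_numpy(dtype=float)
    offset = np.log(series["population"].to_numpy(dtype=float))

    blocks, names = [np.ones((n, 1))], ["intercept"]
    mask = np.ones(n, dtype=bool)
    for cb in crossbases:
        blocks.append(cb.matrix)
        names.extend(cb.column_names())
        mask &= cb.complete
    blocks.append(series["holiday"].to_numpy(dtype=float).reshape(-1, 1))
    names.append("holiday")

    dates = pd.to_datetime(series["date"])
    if day_of_week:
        dow = dates.dt.dayofweek.to_numpy()
        for d in range(1, 7):
            blocks.append((dow == d).astype(float).reshape(-1, 1))
            names.append(f"dow[{d}]")

    stratum_key = dates.dt.strftime("%Y-%m")
    labels = sorted(stratum_key.unique())
    code = {s: i for i, s in enumerate(labels)}
    strata = stratum_key.map(code).to_numpy()

    X = np.hstack(blocks)
    X[~mask] = 0.0  # masked rows never enter the fit; keep entries finite
    return DesignMatrix(
        y=y, offset=offset, X=X, columns=names, strata=strata,
        stratum_labels=labels, mask=mask, subgroup=subgroup,
    )


@dataclass
class FitResult:
    """Coefficients, dispersion-scaled covariance and fit metadata."""

    params: pd.Series
    cov: pd.DataFrame
    dispersion: float
    llf: float  # Poisson log-likelihood at the estimate
    n_used: int
    p: int  # number of estimated parameters (incl. stratum effects)
    qaic: float
    method: str
    dropped: list[str] = field(default_factory=list)
    stratum_effects: pd.Series | None = None

    def block(self, prefix: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Coefficient subvector and covariance block for one term prefix."""
        names = [c for c in self.params.index if c.startswith(prefix + ":")]
        if not names:
            raise KeyError(f"no coefficients with prefix {prefix!r}")
        beta = self.params[names].to_numpy()
        vcov = self.cov.loc[names, names].to_numpy()
        return beta, vcov, names


def _poisson_llf(y: np.ndarray, mu: np.ndarray) -> float:
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Greedy first-kept rank filter: drop later columns aliased to earlier ones."""
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return X, names, []
    keep, dropped = [], []
    q = np.zeros((X.shape[0], 0))
    for j in range(X.shape[1]):
        col = X[:, j]
        resid = col - q @ (q.T @ col)
        norm = np.linalg.norm(resid)
        if norm > 1e-8 * max(1.0, np.linalg.norm(col)):
            keep.append(j)
            q = np.hstack([q, (resid / norm).reshape(-1, 1)])
        else:
            dropped.append(names[j])
    return X[:, keep], [names[j] for j in keep], dropped


def fit_quasipoisson(
    design: DesignMatrix,
    method: str = "indicators",
    dispersion: float | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> FitResult:
    """Fit the quasi-Poisson model; see module docstring for the two routes.

    ``dispersion`` overrides the Pearson estimate of phi (used when comparing
    nested candidates with the largest model's phi, the Q-AIC convention).
    """
    if method == "indicators":
        return _fit_indicators(design, dispersion)
    if method == "absorb":
        return _fit_absorb(design, dispersion, max_iter, tol)
    raise ValueError(f"unknown method {method!r}")


def _fit_indicators(design: DesignMatrix, dispersion: float | None) -> FitResult:
    m = design.mask
    Xfull, names = design.with_indicators()
    X, names, dropped = _drop_aliased(Xfull[m], names)
    y, offset = design.y[m], design.offset[m]

    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
    res = model.fit(scale="X2", tol=1e-12)
    if not res.converged:
        raise RuntimeError(f"IRLS did not converge (deviance {res.deviance:.6g})")
    mu = res.fittedvalues
    p = X.shape[1]
    phi_hat = float(np.sum((y - mu) ** 2 / mu) / (y.size - p))
    phi = phi_hat if dispersion is None else float(dispersion)
    cov = np.asarray(res.cov_params()) / res.scale * phi
    llf = _poisson_llf(y, mu)

    params = pd.Series(res.params, index=names)
    strat_names = [c for c in names if c.startswith("stratum[")]
    main = [c for c in names if not c.startswith("stratum[")]
    return FitResult(
        params=params[main],
        cov=pd.DataFrame(cov, index=names, columns=names).loc[main, main],
        dispersion=phi,
        llf=llf,
        n_used=int(y.size),
        p=p,
        qaic=-2.0 * llf / phi + 2.0 * p,
        method="indicators",
        dropped=dropped,
        stratum_effects=params[strat_names],
    )


def _fit_absorb(
    design: DesignMatrix, dispersion: float | None, max_iter: int, tol: float
) -> FitResult:
    """Profiled IRLS: stratum effects solved in closed form each iteration.

    Given beta, the stratum log-effect that maximizes the Poisson likelihood
    is s_g = log(sum_g y / sum_g exp(offset + X beta)); the beta update is a
    weighted least squares on within-stratum centered covariates.  The
    intercept is absorbed too (strata partition all rows and span it).
    """
    m = design.mask
    keep_cols = [j for j, c in enumerate(design.columns) if c != "intercept"]
    X, names, dropped = _drop_aliased(
        design.X[m][:, keep_cols], [design.columns[j] for j in keep_cols]
    )
    y, offset = design.y[m], design.offset[m]
    strata = design.strata[m]
    groups = np.unique(strata)
    g_index = np.searchsorted(groups, strata)
    n_strata = groups.size
    ysum = np.bincount(g_index, weights=y, minlength=n_strata)
    if np.any(ysum < 0):
        raise ValueError("negative counts")

    beta = np.zeros(X.shape[1])
    dev_prev = np.inf
    for it in range(max_iter):
        eta0 = offset + X @ beta
        mu0 = np.exp(eta0)
        denom = np.bincount(g_index, weights=mu0, minlength=n_strata)
        with np.errstate(divide="ignore"):
            s = np.where(ysum > 0, np.log(np.where(ysum > 0, ysum, 1.0) / denom), -np.inf)
        mu = np.where(np.isfinite(s[g_index]), mu0 * np.exp(s[g_index]), 0.0)
        live = mu > 0
        w = mu[live]
        # working response (minus offset and stratum effect), then center
        z = (y[live] - w) / w + X[live] @ beta
        wsum = np.bincount(g_index[live], weights=w, minlength=n_strata)
        def center(v):
            num = np.bincount(g_index[live], weights=w * v, minlength=n_strata)
            return v - (num / wsum)[g_index[live]]
        Xc = np.column_stack([center(X[live][:, j]) for j in range(X.shape[1])])
        zc = center(z)
        wh = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(Xc * wh[:, None], zc * wh, rcond=None)
        dev = 2.0 * np.sum(
            np.where(y[live] > 0, y[live] * np.log(y[live] / w), 0.0) - (y[live] - w)
        )
        if np.max(np.abs(beta_new - beta)) < tol or abs(dev - dev_prev) < tol:
            beta = beta_new
            break
        beta, dev_prev = beta_new, dev
    else:
        raise RuntimeError(f"profiled IRLS did not converge (deviance {dev:.6g})")

    eta0 = offset + X @ beta
    mu0 = np.exp(eta0)
    denom = np.bincount(g_index, weights=mu0, minlength=n_strata)
    s = np.where(ysum > 0, np.log(np.where(ysum > 0, ysum, 1.0) / denom), -np.inf)
    mu = np.where(np.isfinite(s[g_index]), mu0 * np.exp(s[g_index]), 0.0)
    live = mu > 0
    w = mu[live]
    p = X.shape[1] + n_strata
    phi_hat = float(np.sum((y[live] - w) ** 2 / w) / (live.sum() - p))
    phi = phi_hat if dispersion is None else float(dispersion)
    wsum = np.bincount(g_index[live], weights=w, minlength=n_strata)
    def center(v):
        num = np.bincount(g_index[live], weights=w * v, minlength=n_strata)
        return v - (num / wsum)[g_index[live]]
    Xc = np.column_stack([center(X[live][:, j]) for j in range(X.shape[1])])
    info = (Xc * w[:, None]).T @ Xc  # profiled Fisher information for beta
    cov = phi * np.linalg.inv(info)
    llf = _poisson_llf(y[live], w)  # dead strata (all-zero y, mu=0) contribute 0

    return FitResult(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        dispersion=phi,
        llf=llf,
        n_used=int(live.sum()),
        p=p,
        qaic=-2.0 * llf / phi + 2.0 * p,
        method="absorb",
        dropped=dropped,
        stratum_effects=pd.Series(s, index=[str(g) for g in groups]),
    )


def qaic(fit: FitResult, dispersion: float | None = None) -> float:
    """Q-AIC = -2*loglik/phi + 2p; pass the largest candidate's phi when
    comparing nested models so all candidates share one scale."""
    phi = fit.dispersion if dispersion is None else float(dispersion)
    return -2.0 * fit.llf / phi + 2.0 * fit.p
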