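"""Natural cubic spline bases and the exposure-lag cross-basis.

A distributed lag non-linear model (DLNM) represents the effect of an
exposure series ``x`` on a daily outcome as a smooth surface over the two
dimensions *exposure value* and *lag*.  The surface is parameterized by the
tensor product of two marginal spline bases: an exposure basis ``R`` (natural
cubic spline over the observed concentration range) and a lag basis ``C``
(natural cubic spline over integer lags ``0..L``).  Row ``t`` of the
cross-basis matrix is

    W[t, (j, k)] = sum_{l=0}^{L} R_j(x[t-l]) * C_k(l)

so that a linear model in the columns of ``W`` fits the full exposure-lag
surface.  Columns are ordered with the exposure-basis index ``j`` outer and
the lag-basis index ``k`` inner, i.e. column ``j * df_lag + k``.

Conventions (documented so prediction contrasts are reproducible):

* exposure-dimension interior knots at equally spaced quantiles of the
  observed series (df=3 => 33.3rd / 66.7th percentiles), boundary knots at
  the observed min/max, no intercept (the model intercept and stratum terms
  absorb level);
* lag-dimension interior knots at equally spaced values on the log scale of
  lag, boundary knots at 0 and L, *with* an intercept column so that
  lag-constant effect profiles lie in the span;
* natural splines are linear beyond the boundary knots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import splev

__all__ = [
    "SplineSpec",
    "CrossBasisSpec",
    "CrossBasis",
    "exposure_spline_spec",
    "lag_spline_spec",
    "natural_cubic_basis",
    "build_lag_matrix",
    "build_cross_basis",
]


@dataclass(frozen=True)
class SplineSpec:
    """Specification of one marginal natural cubic spline basis.

    ``df = len(knots) + 1 + intercept`` columns; interior knots strictly
    increasing and strictly inside the boundary pair.
    """

    df: int
    knots: tuple[float, ...]
    boundary: tuple[float, float]
    intercept: bool = False

    def __post_init__(self) -> None:
        a, b = self.boundary
        if not a < b:
            raise ValueError(f"boundary must be increasing, got {self.boundary}")
        k = np.asarray(self.knots, dtype=float)
        if k.size and not np.all(np.diff(k) > 0):
            raise ValueError("interior knots must be strictly increasing")
        if k.size and (k[0] <= a or k[-1] >= b):
            raise ValueError("interior knots must lie strictly inside the boundary")
        expected = len(self.knots) + 1 + int(self.intercept)
        if self.df != expected:
            raise ValueError(
                f"df={self.df} inconsistent with {len(self.knots)} interior "
                f"knots and intercept={self.intercept} (expected {expected})"
            )


def exposure_spline_spec(x: np.ndarray, df: int = 3) -> SplineSpec:
    """Exposure-dimension spec: quantile knots, min/max boundary, no intercept."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need at least two finite observations")
    n_interior = df - 1
    probs = np.linspace(0, 1, n_interior + 2)[1:-1]
    knots = tuple(np.quantile(x, probs))
    return SplineSpec(df=df, knots=knots, boundary=(float(x.min()), float(x.max())))


def lag_spline_spec(maxlag: int, df: int = 3) -> SplineSpec:
    """Lag-dimension spec: log-spaced interior knots on 0..maxlag, intercept."""
    if maxlag < 1:
        raise ValueError("maxlag must be >= 1 for a spline lag basis")
    n_interior = df - 2
    if n_interior < 0:
        raise ValueError("lag df must be >= 2 (intercept plus one column)")
    if n_interior > 0:
        knots = tuple(np.exp(np.linspace(0.0, np.log(maxlag), n_interior + 2))[1:-1])
    else:
        knots = ()
    return SplineSpec(df=df, knots=knots, boundary=(0.0, float(maxlag)), intercept=True)


def _bspline_columns(pts: np.ndarray, t: np.ndarray, der: int = 0) -> np.ndarray:
    """Evaluate every cubic B-spline basis column (or a derivative) at pts."""
    ncoef = len(t) - 4
    out = np.empty((len(pts), ncoef))
    for j in range(ncoef):
        c = np.zeros(ncoef)
        c[j] = 1.0
        out[:, j] = splev(pts, (t, c, 3), der=der)
    return out


def _ns_projection(spec: SplineSpec) -> tuple[np.ndarray, slice, np.ndarray]:
    """Knot vector, retained B-spline columns and the natural-constraint map.

    The natural basis is the cubic B-spline basis (first column dropped when
    no intercept is requested) projected onto the null space of the
    second-derivative constraints at the two boundary knots.
    """
    a, b = spec.boundary
    t = np.concatenate(([a] * 4, np.asarray(spec.knots, dtype=float), [b] * 4))
    ncoef = len(t) - 4
    cols = slice(0, ncoef) if spec.intercept else slice(1, ncoef)
    const = _bspline_columns(np.array([a, b]), t, der=2)[:, cols]
    q = np.linalg.qr(const.T, mode="complete")[0][:, 2:]
    return t, cols, q


def natural_cubic_basis(x: np.ndarray, spec: SplineSpec) -> np.ndarray:
    """Evaluate the natural cubic spline basis at ``x``.

    Returns an ``(n, spec.df)`` matrix.  Each column is cubic between knots,
    C2 everywhere, and linear beyond the boundary knots (values outside the
    boundary are continued linearly from the boundary value and slope).
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    a, b = spec.boundary
    t, cols, q = _ns_projection(spec)

    out = np.empty((x.size, spec.df))
    inside = (x >= a) & (x <= b)
    if inside.any():
        out[inside] = _bspline_columns(x[inside], t)[:, cols] @ q
    for bound, mask in ((a, x < a), (b, x > b)):
        if mask.any():
            pt = np.array([bound])
            val = (_bspline_columns(pt, t)[:, cols] @ q)[0]
            slope = (_bspline_columns(pt, t, der=1)[:, cols] @ q)[0]
            out[mask] = val + np.outer(x[mask] - bound, slope)
    return out[0] if scalar else out


def build_lag_matrix(x: np.ndarray, maxlag: int) -> np.ndarray:
    """Matrix Q with Q[t, l] = x[t-l]; entries with t < l are NaN.

    Rows ``t < maxlag`` have incomplete lag history and carry NaN in the
    unavailable cells; downstream code flags and excludes them.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if maxlag < 0:
        raise ValueError("maxlag must be nonnegative")
    if maxlag >= n:
        raise ValueError(f"maxlag={maxlag} must be shorter than the series (n={n})")
    q = np.full((n, maxlag + 1), np.nan)
    for lag in range(maxlag + 1):
        q[lag:, lag] = x[: n - lag] if lag else x
    return q


@dataclass(frozen=True)
class CrossBasisSpec:
    """Cross-basis parameters: exposure spline, lag spline, maximal lag."""

    var_spec: SplineSpec
    lag_spec: SplineSpec
    maxlag: int

    def __post_init__(self) -> None:
        if self.maxlag < 1:
            raise ValueError("maxlag must be >= 1")
        if self.lag_spec.boundary != (0.0, float(self.maxlag)):
            raise ValueError("lag basis boundary must be (0, maxlag)")

    @property
    def ncols(self) -> int:
        return self.var_spec.df * self.lag_spec.df


@dataclass
class CrossBasis:
    """One exposure's cross-basis matrix plus prediction metadata.

    ``matrix`` is ``n_days x (df_var * df_lag)`` with the documented
    (j outer, k inner) column ordering; rows with incomplete lag history
    (``t < maxlag``) are NaN and flagged False in ``complete``.
    """

    matrix: np.ndarray
    spec: CrossBasisSpec
    name: str
    complete: np.ndarray = field(repr=False)

    @property
    def maxlag(self) -> int:
        return self.spec.maxlag

    def column_names(self) -> list[str]:
        dv, dl = self.spec.var_spec.df, self.spec.lag_spec.df
        return [f"{self.name}:v{j + 1}:l{k + 1}" for j in range(dv) for k in range(dl)]

    def var_basis(self, x) -> np.ndarray:
        """Exposure basis R evaluated at new values (for contrasts)."""
        return natural_cubic_basis(x, self.spec.var_spec)

    def lag_basis(self) -> np.ndarray:
        """Lag basis C at integer lags 0..maxlag, shape (maxlag+1, df_lag)."""
        return natural_cubic_basis(np.arange(self.maxlag + 1.0), self.spec.lag_spec)


def build_cross_basis(
    x: np.ndarray,
    spec: CrossBasisSpec | None = None,
    name: str = "exposure",
    df_var: int = 3,
    df_lag: int = 3,
    maxlag: int = 14,
) -> CrossBasis:
    """Build the cross-basis matrix for one exposure series.

    When ``spec`` is omitted it is derived from the data with the documented
    knot conventions (quantile knots for exposure, log-spaced for lag).
    """
    x = np.asarray(x, dtype=float)
    if spec is None:
        spec = CrossBasisSpec(
            var_spec=exposure_spline_spec(x, df=df_var),
            lag_spec=lag_spline_spec(maxlag, df=df_lag),
            maxlag=maxlag,
        )
    if x.size <= spec.maxlag:
        raise ValueError("series must be longer than maxlag")

    lagmat = build_lag_matrix(x, spec.maxlag)
    cmat = natural_cubic_basis(np.arange(spec.maxlag + 1.0), spec.lag_spec)
    n = x.size
    w = np.zeros((n, spec.ncols))
    for lag in range(spec.maxlag + 1):
        col = lagmat[:, lag]
        ok = ~np.isnan(col)
        r = natural_cubic_basis(col[ok], spec.var_spec)
        # accumulate R_j(x_{t-l}) * C_k(l) into column j*df_lag + k
        w[ok] += np.einsum("tj,k->tjk", r, cmat[lag]).reshape(ok.sum(), -1)
    complete = np.ones(n, dtype=bool)
    complete[: spec.maxlag] = False
    w[~complete] = np.nan
    return CrossBasis(matrix=w, spec=spec, name=name, complete=complete)
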