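"""Natural cubic splines, lag matrix and cross-basis construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lagrisk.basis import (
    CrossBasisSpec,
    SplineSpec,
    build_cross_basis,
    build_lag_matrix,
    exposure_spline_spec,
    lag_spline_spec,
    natural_cubic_basis,
)


def brute_force_cross_basis(x, var_spec, lag_spec, maxlag):
    """Independent triple-loop construction of W[t,(j,k)]."""
    n = len(x)
    dv, dl = var_spec.df, lag_spec.df
    lags = np.arange(maxlag + 1.0)
    w = np.full((n, dv * dl), np.nan)
    for t in range(maxlag, n):
        row = np.zeros(dv * dl)
        for j in range(dv):
            for k in range(dl):
                acc = 0.0
                for lag in range(maxlag + 1):
                    r = natural_cubic_basis(np.array([x[t - lag]]), var_spec)[0, j]
                    c = natural_cubic_basis(np.array([lags[lag]]), lag_spec)[0, k]
                    acc += r * c
                row[j * dl + k] = acc
        w[t] = row
    return w


class TestNaturalCubicBasis:
    def test_dimension_bookkeeping(self):
        x = np.linspace(0, 100, 50)
        spec = exposure_spline_spec(x, df=3)
        assert len(spec.knots) == 2  # df=3 => 2 interior knots, no intercept
        assert natural_cubic_basis(x, spec).shape == (50, 3)

    def test_linear_beyond_boundary(self):
        """Natural splines are linear outside the boundary knots: second
        finite differences of every column vanish there."""
        rng = np.random.default_rng(0)
        spec = exposure_spline_spec(rng.uniform(0, 10, 200), df=4)
        for base in (-5.0, 15.0):
            pts = base + np.array([0.0, 1e-3, 2e-3])
            b = natural_cubic_basis(pts, spec)
            assert np.abs(b[2] - 2 * b[1] + b[0]).max() < 1e-8

    def test_linear_functions_in_span(self):
        """g(x)=x lies in span(basis) + intercept: the least-squares
        projection reproduces x to numerical precision."""
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 50, 300)
        b = natural_cubic_basis(x, exposure_spline_spec(x, df=3))
        a = np.column_stack([np.ones_like(x), b])
        coef, *_ = np.linalg.lstsq(a, x, rcond=None)
        assert np.abs(a @ coef - x).max() < 1e-8

    def test_continuity_of_second_derivative(self):
        """C2 at an interior knot: second differences agree across the knot."""
        x = np.linspace(0, 10, 500)
        spec = SplineSpec(df=3, knots=(3.0, 7.0), boundary=(0.0, 10.0))
        h = 1e-4
        for knot in spec.knots:
            pts = knot + h * np.arange(-2, 3)
            b = natural_cubic_basis(pts, spec)
            d2 = (b[:-2] - 2 * b[1:-1] + b[2:]) / h**2
            assert np.abs(d2[0] - d2[-1]).max() < 1e-2

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            SplineSpec(df=3, knots=(5.0, 2.0), boundary=(0.0, 10.0))
        with pytest.raises(ValueError, match="inside"):
            SplineSpec(df=3, knots=(0.0, 5.0), boundary=(0.0, 10.0))
        with pytest.raises(ValueError, match="df"):
            SplineSpec(df=5, knots=(5.0,), boundary=(0.0, 10.0))
        with pytest.raises(ValueError, match="finite"):
            natural_cubic_basis(
                np.array([np.nan]), SplineSpec(df=3, knots=(4.0, 6.0), boundary=(0.0, 10.0))
            )


class TestLagMatrix:
    def test_lag_zero_is_identity(self):
        x = np.arange(5.0)
        assert np.array_equal(build_lag_matrix(x, 0)[:, 0], x)

    def test_hand_readable_shift(self):
        q = build_lag_matrix(np.array([1.0, 2.0, 3.0, 4.0]), 2)
        assert np.array_equal(q[3], [4.0, 3.0, 2.0])
        assert np.isnan(q[0, 1]) and np.isnan(q[1, 2])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_double_loop(self, seed):
        x = np.random.default_rng(seed).normal(size=40)
        q = build_lag_matrix(x, 14)
        for t in range(40):
            for lag in range(15):
                if t >= lag:
                    assert q[t, lag] == x[t - lag]
                else:
                    assert np.isnan(q[t, lag])

    def test_too_long_lag_rejected(self):
        with pytest.raises(ValueError, match="maxlag"):
            build_lag_matrix(np.arange(5.0), 5)


class TestCrossBasis:
    def test_column_count_and_flags(self):
        x = np.random.default_rng(2).uniform(0, 60, 100)
        cb = build_cross_basis(x, name="so2", df_var=3, df_lag=3, maxlag=14)
        assert cb.matrix.shape == (100, 9)  # 3 df exposure x 3 df lag
        assert (~cb.complete).sum() == 14
        assert np.isnan(cb.matrix[:14]).all()
        assert np.isfinite(cb.matrix[14:]).all()

    def test_constant_series_factorizes(self):
        """x == c: every complete row equals R(c) (x) sum_l C(l) and all
        complete rows are identical."""
        c = 5.0
        x = np.full(40, c)
        var_spec = SplineSpec(df=3, knots=(4.0, 6.0), boundary=(0.0, 10.0))
        spec = CrossBasisSpec(var_spec=var_spec, lag_spec=lag_spline_spec(14, 3), maxlag=14)
        cb = build_cross_basis(x, spec=spec, name="x")
        r = natural_cubic_basis(np.array([c]), var_spec)[0]
        csum = natural_cubic_basis(np.arange(15.0), spec.lag_spec).sum(axis=0)
        expected = np.outer(r, csum).ravel()
        complete = cb.matrix[cb.complete]
        assert np.allclose(complete, expected, atol=1e-12)
        assert np.allclose(complete, complete[0], atol=1e-12)

    def test_matches_triple_loop(self):
        x = np.random.default_rng(3).uniform(0, 80, 60)
        cb = build_cross_basis(x, name="x", df_var=3, df_lag=3, maxlag=14)
        ref = brute_force_cross_basis(x, cb.spec.var_spec, cb.spec.lag_spec, 14)
        assert np.nanmax(np.abs(cb.matrix - ref)) < 1e-10

    def test_lag_constant_profile_gives_moving_average(self):
        """The lag basis contains the constant profile (it has an intercept);
        contracting a var-basis block with the coefficients reproducing a
        constant lag profile yields the 15-day moving sum of R_j(x)."""
        x = np.random.default_rng(4).uniform(0, 80, 80)
        cb = build_cross_basis(x, name="x", df_var=3, df_lag=3, maxlag=14)
        cmat = cb.lag_basis()
        a, *_ = np.linalg.lstsq(cmat, np.ones(15), rcond=None)
        assert np.abs(cmat @ a - 1).max() < 1e-10  # constant really in span
        r = cb.var_basis(x)
        q = build_lag_matrix(x, 14)
        for j in range(3):
            block = cb.matrix[:, j * 3 : (j + 1) * 3]
            moving_sum = np.array(
                [cb.var_basis(q[t])[:, j].sum() for t in range(14, 80)]
            )
            assert np.allclose(block[14:] @ a, moving_sum, atol=1e-8)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="longer than maxlag"):
            build_cross_basis(np.random.default_rng(5).uniform(1, 2, 10), maxlag=14)
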