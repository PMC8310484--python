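import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mvdlnm as mv
from mvdlnm.errors import BasisError
from mvdlnm.lagbasis import natural_spline_basis, temperature_basis


# --- independent oracles -----------------------------------------------------

def deboor(x, t, k, i):
    """Cox-de Boor recursion, written independently of scipy."""
    if k == 0:
        return 1.0 if t[i] <= x < t[i + 1] else 0.0
    left = 0.0
    if t[i + k] > t[i]:
        left = (x - t[i]) / (t[i + k] - t[i]) * deboor(x, t, k - 1, i)
    right = 0.0
    if t[i + k + 1] > t[i + 1]:
        right = (t[i + k + 1] - x) / (t[i + k + 1] - t[i + 1]) * deboor(
            x, t, k - 1, i + 1
        )
    return left + right


def truncated_power_natural_basis(x, knots):
    """Natural cubic spline space spanned by {1, x, d_k - d_{K-1}} with
    d_k(x) = [(x-xi_k)+^3 - (x-xi_K)+^3] / (xi_K - xi_k); knots include the
    boundaries."""
    x = np.asarray(x, dtype=float)
    xi = np.asarray(knots, dtype=float)
    K = len(xi)

    def d(k):
        return (
            np.clip(x - xi[k], 0, None) ** 3 - np.clip(x - xi[K - 1], 0, None) ** 3
        ) / (xi[K - 1] - xi[k])

    cols = [np.ones_like(x), x] + [d(k) - d(K - 2) for k in range(K - 2)]
    return np.column_stack(cols)


def hat_matrix(B):
    return B @ np.linalg.pinv(B.T @ B) @ B.T


# --- lag matrices ------------------------------------------------------------

class TestLagMatrix:
    def test_worked_matrix(self, worked_lagm):
        expected = np.array(
            [[60, 51, 62], [73, 60, 51], [61, 73, 60], [55, 61, 73]], dtype=float
        )
        assert worked_lagm.valid_rows.sum() == 4
        np.testing.assert_array_equal(
            worked_lagm.values[worked_lagm.valid_rows], expected
        )

    def test_zero_lag_is_identity(self):
        series = [3.0, 1.0, 4.0, 1.5]
        lm = mv.build_lag_matrix(series, 0)
        np.testing.assert_array_equal(lm.values[:, 0], series)
        assert lm.valid_rows.all()

    def test_constant_series(self):
        lm = mv.build_lag_matrix(np.full(10, 7.0), 3)
        assert np.all(lm.values[lm.valid_rows] == 7.0)

    def test_nan_breaks_following_windows(self):
        x = np.arange(20.0)
        x[8] = np.nan
        lm = mv.build_lag_matrix(x, 3)
        # rows 8..11 have the NaN inside their window
        assert not lm.valid_rows[8:12].any()
        assert lm.valid_rows[12:].all()
        assert lm.valid_rows[3:8].all()

    def test_excessive_lag_rejected(self):
        with pytest.raises(BasisError):
            mv.build_lag_matrix([1.0, 2.0], 2)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        n=st.integers(5, 40),
        lag=st.integers(0, 4),
        seed=st.integers(0, 2**16),
    )
    def test_lag_identity_property(self, n, lag, seed):
        x = np.random.default_rng(seed).normal(size=n)
        lm = mv.build_lag_matrix(x, lag)
        for t in range(lag, n):
            for j in range(lag + 1):
                assert lm.values[t, j] == x[t - j]


# --- exposure basis ----------------------------------------------------------

class TestTemperatureBasis:
    KNOTS = (15.8, 27.6, 30.3)
    BOUND = (5.6, 33.0)

    def test_matches_de_boor_recursion(self):
        t = np.r_[[self.BOUND[0]] * 3, self.KNOTS, [self.BOUND[1]] * 3]
        xs = np.linspace(6.0, 32.9, 23)
        ours = temperature_basis(xs, self.KNOTS, self.BOUND, intercept=True)
        for gi, x in enumerate(xs):
            ref = [deboor(x, t, 2, i) for i in range(6)]
            np.testing.assert_allclose(ours[gi], ref, atol=1e-12)

    def test_five_columns_without_intercept(self):
        B = temperature_basis([20.0], self.KNOTS, self.BOUND)
        assert B.shape == (1, 5)

    def test_partition_of_unity_with_intercept(self):
        xs = np.linspace(*self.BOUND, 50)
        B = temperature_basis(xs, self.KNOTS, self.BOUND, intercept=True)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(B >= -1e-12)

    def test_boundary_endpoints(self):
        B = temperature_basis(
            [self.BOUND[0], self.BOUND[1]], self.KNOTS, self.BOUND, intercept=True
        )
        np.testing.assert_allclose(B[0], [1, 0, 0, 0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(B[1], [0, 0, 0, 0, 0, 1], atol=1e-12)

    def test_bad_knots_rejected(self):
        with pytest.raises(BasisError):
            temperature_basis([20.0], (30, 20, 10), self.BOUND)
        with pytest.raises(BasisError):
            temperature_basis([20.0], (1.0, 20.0, 30.0), self.BOUND)


# --- lag knots and lag basis -------------------------------------------------

class TestLagKnots:
    def test_closed_form_l30(self):
        np.testing.assert_allclose(
            mv.log_lag_knots(30), 30.0 ** (np.array([1, 2, 3]) / 4)
        )

    @pytest.mark.parametrize("L", [10, 20, 30])
    def test_inside_range_and_monotone(self, L):
        k = mv.log_lag_knots(L)
        assert np.all(np.diff(k) > 0)
        assert np.all((k > 1) & (k < L))

    def test_monotone_in_max_lag(self):
        k10, k20, k30 = (mv.log_lag_knots(L) for L in (10, 20, 30))
        assert np.all(k10 < k20) and np.all(k20 < k30)

    def test_tiny_lag_rejected(self):
        with pytest.raises(BasisError):
            mv.log_lag_knots(1)


class TestLagSplineBasis:
    @pytest.mark.parametrize("L", [10, 20, 30])
    def test_five_degrees_of_freedom(self, L):
        C = mv.lag_spline_basis(np.arange(L + 1), mv.log_lag_knots(L), L)
        assert C.shape == (L + 1, 5)
        assert np.linalg.matrix_rank(C) == 5

    def test_zero_second_derivative_at_boundaries(self):
        L = 20
        knots = mv.log_lag_knots(L)
        h = 1e-5

        def basis(v):
            return natural_spline_basis(
                np.asarray(v), knots, (0.0, L), intercept=True
            )

        for b in (0.0, float(L)):
            second = (basis([b - h]) - 2 * basis([b]) + basis([b + h])) / h**2
            np.testing.assert_allclose(second, 0.0, atol=1e-4)

    def test_linear_beyond_boundaries(self):
        L = 10
        knots = mv.log_lag_knots(L)
        xs = np.array([-3.0, -2.0, -1.0, L + 1.0, L + 2.0, L + 3.0])
        B = natural_spline_basis(xs, knots, (0.0, L), intercept=True)
        # second differences of equally spaced points on a line vanish
        np.testing.assert_allclose(B[0] - 2 * B[1] + B[2], 0.0, atol=1e-10)
        np.testing.assert_allclose(B[3] - 2 * B[4] + B[5], 0.0, atol=1e-10)

    def test_same_span_as_truncated_power_oracle(self):
        L = 20
        interior = mv.log_lag_knots(L)
        lags = np.linspace(0, L, 81)
        ours = natural_spline_basis(lags, interior, (0.0, L), intercept=True)
        oracle = truncated_power_natural_basis(lags, np.r_[0.0, interior, L])
        assert ours.shape[1] == oracle.shape[1] == 5
        np.testing.assert_allclose(
            hat_matrix(ours), hat_matrix(oracle), atol=1e-10
        )


# --- cross-basis -------------------------------------------------------------

class TestCrossBasis:
    def _random_cb(self, seed=0, n=50, L=5):
        rng = np.random.default_rng(seed)
        x = 20 + 5 * rng.standard_normal(n)
        lagm = mv.build_lag_matrix(x, L)
        return x, lagm, mv.build_crossbasis(lagm)

    def test_dimensions_and_validity(self):
        _, lagm, cb = self._random_cb()
        assert cb.design.shape[1] == 25
        assert (cb.valid_rows == lagm.valid_rows).all()
        assert np.isfinite(cb.design[cb.valid_rows]).all()
        assert np.isnan(cb.design[~cb.valid_rows]).all()

    def test_brute_force_double_sum(self):
        x, lagm, cb = self._random_cb(seed=3)
        rng = np.random.default_rng(4)
        beta = rng.standard_normal(25)
        C = cb.lag_basis
        got = cb.design[cb.valid_rows] @ beta
        rows = np.flatnonzero(cb.valid_rows)
        expected = np.empty(rows.size)
        for out_i, t in enumerate(rows):
            acc = 0.0
            for lag in range(cb.max_lag + 1):
                A = cb.exposure_basis(np.array([x[t - lag]]))[0]
                for i in range(5):
                    for j in range(5):
                        acc += A[i] * C[lag, j] * beta[i * 5 + j]
            expected[out_i] = acc
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_constant_exposure_gives_identical_rows(self):
        lagm = mv.build_lag_matrix(np.full(30, 20.0), 4)
        cb = mv.build_crossbasis(
            lagm, var_knots=(18.0, 21.0, 22.0), var_boundary=(15.0, 25.0)
        )
        rows = cb.design[cb.valid_rows]
        np.testing.assert_allclose(rows - rows[0], 0.0, atol=1e-12)

    def test_zero_lag_collapses_to_exposure_basis(self):
        rng = np.random.default_rng(5)
        x = 20 + 5 * rng.standard_normal(40)
        lagm = mv.build_lag_matrix(x, 0)
        cb = mv.build_crossbasis(lagm)
        expected = temperature_basis(x, cb.var_knots, cb.var_boundary)
        np.testing.assert_allclose(cb.design, expected, atol=1e-12)

    def test_time_shift_equivariance(self):
        rng = np.random.default_rng(6)
        x = 20 + 5 * rng.standard_normal(60)
        lag = 3
        cb_a = mv.build_crossbasis(
            mv.build_lag_matrix(x, lag),
            var_knots=(17.0, 22.0, 25.0), var_boundary=(5.0, 35.0),
        )
        cb_b = mv.build_crossbasis(
            mv.build_lag_matrix(x[10:], lag),
            var_knots=(17.0, 22.0, 25.0), var_boundary=(5.0, 35.0),
        )
        np.testing.assert_allclose(
            cb_a.design[10 + lag:], cb_b.design[lag:], atol=1e-12
        )


# --- seasonal basis ----------------------------------------------------------

class TestSeasonalBasis:
    def test_full_study_period(self):
        sb = mv.seasonal_basis(1826, n_years=5)
        assert sb.design.shape == (1826, 40)
        assert np.linalg.matrix_rank(sb.design) == 40

    def test_single_year(self):
        sb = mv.seasonal_basis(365, n_years=1)
        assert sb.df == 8

    def test_saturated_rejected(self):
        with pytest.raises(BasisError):
            mv.seasonal_basis(30, total_df=30)
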