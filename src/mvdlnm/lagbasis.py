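"""Spline bases for the exposure-lag-response surface.

The DLNM represents the bidimensional temperature-lag surface through a
*cross-basis*: a quadratic B-spline over the temperature axis (knots at the
10th/75th/90th percentiles, boundary at the observed range) crossed with a
natural cubic spline over the lag axis (5 df, interior knots equally spaced
on the log-lag scale).  Seasonality is absorbed by a long natural cubic
spline in the day index with 8 degrees of freedom per year.

All constructions are pure functions of their inputs.  Rows whose lag
window crosses a missing day are invalidated, never interpolated.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.interpolate import BSpline

from .errors import BasisError

__all__ = [
    "LagMatrix",
    "CrossBasis",
    "SeasonalBasis",
    "build_lag_matrix",
    "temperature_basis",
    "natural_spline_basis",
    "log_lag_knots",
    "lag_spline_basis",
    "build_crossbasis",
    "seasonal_basis",
]


# ---------------------------------------------------------------------------
# lag matrices


@dataclasses.dataclass(frozen=True)
class LagMatrix:
    """n x (L+1) matrix whose column j holds the series lagged j days.

    Rows without a complete lag window (the first L rows, and any row whose
    window crosses a missing value) are invalid; their entries are NaN.
    """

    values: np.ndarray
    max_lag: int
    valid_rows: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]


def build_lag_matrix(series, max_lag: int) -> LagMatrix:
    """Arrange a daily series and its lags 1..L as columns.

    ``values[t, j] = series[t - j]``; the first ``max_lag`` rows, and rows
    whose window covers a NaN in the input, are marked invalid.
    """
    x = np.asarray(series, dtype=float)
    n = x.shape[0]
    if max_lag < 0:
        raise BasisError("max_lag must be non-negative")
    if max_lag >= n:
        raise BasisError(f"max_lag={max_lag} >= series length {n}")
    values = np.full((n, max_lag + 1), np.nan)
    for j in range(max_lag + 1):
        values[j:, j] = x[: n - j]
    valid = np.isfinite(values).all(axis=1)
    return LagMatrix(values=values, max_lag=max_lag, valid_rows=valid)


# ---------------------------------------------------------------------------
# B-spline and natural-spline primitives


def _bspline_design(x, t, degree, deriv=0, extrapolate=True):
    """Dense design matrix of all B-spline basis functions on knot vector t."""
    n_basis = len(t) - degree - 1
    spl = BSpline(np.asarray(t, float), np.eye(n_basis), degree,
                  extrapolate=extrapolate)
    if deriv:
        spl = spl.derivative(deriv)
    out = spl(np.asarray(x, float))
    return np.atleast_2d(out)


def temperature_basis(
    x,
    knots,
    boundary,
    degree: int = 2,
    intercept: bool = False,
) -> np.ndarray:
    """Quadratic B-spline basis for the temperature axis.

    With the conventional three interior knots and ``intercept=False`` this
    yields vx = 5 columns.  Values outside the boundary follow the B-spline
    recursion (polynomial extrapolation of the end pieces).
    """
    knots = np.asarray(knots, dtype=float)
    lo, hi = float(boundary[0]), float(boundary[1])
    if np.any(np.diff(knots) <= 0):
        raise BasisError("interior knots must be strictly increasing")
    if np.any(knots <= lo) or np.any(knots >= hi):
        raise BasisError("interior knots must lie strictly inside the boundary")
    t = np.r_[[lo] * (degree + 1), knots, [hi] * (degree + 1)]
    basis = _bspline_design(x, t, degree)
    # at the upper boundary the last basis function carries the unit mass
    upper = np.asarray(x, float) == hi
    if np.any(upper):
        basis[upper] = 0.0
        basis[upper, -1] = 1.0
    if not intercept:
        basis = basis[:, 1:]
    return basis


def natural_spline_basis(
    x,
    interior_knots,
    boundary,
    intercept: bool = False,
) -> np.ndarray:
    """Natural cubic spline basis: cubic B-splines constrained to zero
    second derivative at the boundary knots, hence linear beyond them.

    The construction projects the full cubic B-spline basis onto the null
    space of the boundary curvature constraints (QR of the constraint
    matrix); points outside the boundary are filled in by first-order
    Taylor expansion about the nearest boundary knot, preserving the
    linear tail.  Column count: ``len(interior_knots) + 1 + intercept``.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    interior = np.asarray(interior_knots, dtype=float)
    lo, hi = float(boundary[0]), float(boundary[1])
    if interior.size and (interior.min() <= lo or interior.max() >= hi):
        raise BasisError("interior knots must lie strictly inside the boundary")
    t = np.r_[[lo] * 4, interior, [hi] * 4]

    def full(v, deriv=0):
        return _bspline_design(v, t, 3, deriv=deriv, extrapolate=False)

    inside = (x >= lo) & (x <= hi)
    n_basis = len(t) - 4
    base = np.zeros((x.size, n_basis))
    if inside.any():
        base[inside] = full(x[inside])
    for bnd, mask in ((lo, x < lo), (hi, x > hi)):
        if mask.any():
            b0 = full([bnd])
            b1 = full([bnd], deriv=1)
            base[mask] = b0 + (x[mask, None] - bnd) * b1
    const = full([lo, hi], deriv=2)  # 2 x n_basis curvature constraints
    if not intercept:
        base = base[:, 1:]
        const = const[:, 1:]
    q, _ = np.linalg.qr(const.T, mode="complete")
    out = base @ q[:, 2:]
    return out[0] if scalar else out


def log_lag_knots(max_lag: int, n_knots: int = 3) -> np.ndarray:
    """Interior lag knots equally spaced on the log scale in (1, L).

    The spacing is anchored at log(1) = 0, so the knots are
    ``L**(k/(n_knots+1))`` for k = 1..n_knots.
    """
    if max_lag < 2:
        raise BasisError(
            f"max_lag={max_lag} is too small to host {n_knots} interior log knots"
        )
    fracs = np.arange(1, n_knots + 1) / (n_knots + 1)
    return float(max_lag) ** fracs


def lag_spline_basis(lags, knots, max_lag: int | None = None) -> np.ndarray:
    """Natural cubic spline basis over the lag axis, with intercept.

    With three interior knots this gives the conventional vl = 5 degrees of
    freedom; boundary knots sit at lag 0 and lag L.
    """
    lags = np.asarray(lags, dtype=float)
    if max_lag is None:
        max_lag = int(lags.max())
    return natural_spline_basis(lags, knots, (0.0, float(max_lag)), intercept=True)


# ---------------------------------------------------------------------------
# cross-basis


@dataclasses.dataclass(frozen=True)
class CrossBasis:
    """Tensor-product design matrix of the exposure-lag-response surface.

    ``design[t, i*vl + j] = sum_l A_i(x_{t-l}) * C_j(l)`` where A is the
    exposure basis and C the lag basis.  ``lag_basis`` holds C evaluated at
    lags 0..L (shape (L+1) x vl) so predictions can re-contract it.
    """

    design: np.ndarray
    valid_rows: np.ndarray
    var_knots: np.ndarray
    var_boundary: tuple[float, float]
    var_degree: int
    lag_knots: np.ndarray
    lag_basis: np.ndarray
    max_lag: int
    centering_value: float

    @property
    def var_df(self) -> int:
        return self.design.shape[1] // self.lag_basis.shape[1]

    @property
    def lag_df(self) -> int:
        return self.lag_basis.shape[1]

    def exposure_basis(self, x) -> np.ndarray:
        """The exposure-dimension basis evaluated at temperature(s) x."""
        return temperature_basis(
            np.atleast_1d(x), self.var_knots, self.var_boundary, self.var_degree
        )


def build_crossbasis(
    lagm: LagMatrix,
    *,
    var_knots=None,
    var_boundary=None,
    var_degree: int = 2,
    var_knot_percentiles=(10, 75, 90),
    lag_knots=None,
    n_lag_knots: int = 3,
    centering: float | str = "median",
) -> CrossBasis:
    """Build the cross-basis from a lag matrix of temperatures.

    Knots default to the stated percentiles of the observed temperatures on
    the analysis window (after missingness filtering) with boundary knots
    at the observed min/max; lag knots default to the log-spaced placement.
    A degenerate lag dimension (L = 0) collapses the lag basis to the
    constant 1, so the cross-basis equals the plain exposure basis.
    """
    L = lagm.max_lag
    obs = lagm.values[:, 0]
    obs = obs[np.isfinite(obs)]
    if obs.size == 0:
        raise BasisError("no observed exposure values")
    if var_boundary is None:
        var_boundary = (float(obs.min()), float(obs.max()))
    if var_knots is None:
        var_knots = np.percentile(obs, var_knot_percentiles)
    var_knots = np.asarray(var_knots, dtype=float)

    if L == 0:
        lag_knots = np.asarray([], dtype=float)
        C = np.ones((1, 1))
    else:
        if lag_knots is None:
            lag_knots = log_lag_knots(L, n_lag_knots)
        lag_knots = np.asarray(lag_knots, dtype=float)
        C = lag_spline_basis(np.arange(L + 1), lag_knots, L)
        if L + 1 < C.shape[1]:
            warnings.warn(
                f"lag basis has {C.shape[1]} df on only {L + 1} lag points; "
                "the cross-basis will be rank deficient",
                stacklevel=2,
            )

    vl = C.shape[1]
    n = lagm.n
    valid = lagm.valid_rows
    Q = lagm.values[valid]  # m x (L+1)
    # A_all[t, l, i] = A_i(x_{t-l}) for valid rows
    A_flat = temperature_basis(Q.ravel(), var_knots, var_boundary, var_degree)
    vx = A_flat.shape[1]
    A_all = A_flat.reshape(Q.shape[0], L + 1, vx)
    design_valid = np.einsum("tli,lj->tij", A_all, C).reshape(Q.shape[0], vx * vl)
    design = np.full((n, vx * vl), np.nan)
    design[valid] = design_valid

    if centering == "median":
        centering_value = float(np.median(obs))
    else:
        centering_value = float(centering)

    return CrossBasis(
        design=design,
        valid_rows=valid,
        var_knots=var_knots,
        var_boundary=(float(var_boundary[0]), float(var_boundary[1])),
        var_degree=var_degree,
        lag_knots=lag_knots,
        lag_basis=C,
        max_lag=L,
        centering_value=centering_value,
    )


# ---------------------------------------------------------------------------
# seasonal adjustment


@dataclasses.dataclass(frozen=True)
class SeasonalBasis:
    """Natural cubic spline in the day index absorbing season and trend."""

    design: np.ndarray
    df_per_year: float
    n_years: float

    @property
    def df(self) -> int:
        return self.design.shape[1]


def seasonal_basis(
    n_days: int,
    n_years: float | None = None,
    df_per_year: int = 8,
    total_df: int | None = None,
) -> SeasonalBasis:
    """One long natural cubic spline over the day index with
    ``df_per_year * n_years`` degrees of freedom (no intercept column).

    Interior knots sit at equally spaced quantiles of the day index.  For
    sub-year windows pass ``total_df`` directly (the per-year convention is
    undefined below one year).
    """
    if n_years is None:
        n_years = n_days / 365.25
    if total_df is None:
        total_df = int(round(df_per_year * n_years))
    if total_df < 2:
        raise BasisError("seasonal spline needs at least 2 df")
    if total_df >= n_days:
        raise BasisError(
            f"seasonal spline with {total_df} df is saturated on {n_days} days"
        )
    t = np.arange(n_days, dtype=float)
    n_interior = total_df - 1
    probs = np.arange(1, n_interior + 1) / (n_interior + 1)
    interior = np.quantile(t, probs)
    design = natural_spline_basis(t, interior, (t[0], t[-1]), intercept=False)
    return SeasonalBasis(design=design, df_per_year=df_per_year, n_years=n_years)
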