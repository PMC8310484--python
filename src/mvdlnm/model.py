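"""Poisson DLNM fitting, the overall significance test, and relative-risk
prediction.

The model for daily deaths mu_t is

    log(mu_t) = alpha + s(x_t, l; beta) + b1*O3_t + b2*PM2.5_t + f(t; theta)
                [+ gamma * sum(x_sL)]            (MV_adjust)
                [+ offset(log(sum(x_sL)))]       (MV_DLNM)

where s(.) is the cross-basis of temperature over lags 0..L, f(.) the
seasonal spline, and sum(x_sL) the sum of the previous m days' deaths.
Estimation is iteratively reweighted least squares (Poisson log link) to a
relative deviance change below 1e-8, at most 100 iterations.  Transformed
non-integer outcomes (sum/AR/PCA strategies) are scored by the same
quasi-likelihood equations.  Coefficient covariance is quasi-Poisson by
default — scaled by the Pearson chi-square dispersion estimate, as is
standard for daily-mortality series, whose counts are overdispersed; pass
``dispersion=1.0`` for the pure Poisson covariance.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.linalg import pinvh

from .data_io import DailySeries
from .errors import ModelFitError, PoissonSupportError
from .lagbasis import (
    CrossBasis,
    SeasonalBasis,
    build_crossbasis,
    build_lag_matrix,
    seasonal_basis,
)
from .transforms import OutcomeSpec, lag_sum_excluding_current, mv_ar, mv_pca, mv_sum

__all__ = ["FitResult", "RRPrediction", "fit_dlnm", "fit_series",
           "overall_pvalue", "predict_rr"]


@dataclasses.dataclass
class FitResult:
    """Coefficients, covariance and test machinery of a fitted (MV-)DLNM.

    ``deviance`` is the (unscaled) model deviance; ``deviance_history`` is
    the IRLS iteration trace, which lives on the dispersion-scaled axis
    when the dispersion is estimated.  ``scale`` is the dispersion estimate
    applied to ``vcov`` (1.0 for a pure Poisson fit).
    """

    coef: np.ndarray
    vcov: np.ndarray
    names: list[str]
    crossbasis_index: np.ndarray
    overall_p: float
    converged: bool
    n_used: int
    deviance: float
    llf: float
    deviance_history: list[float]
    spec: OutcomeSpec
    scale: float
    # retained model arrays (valid rows only) so LRT / diagnostics can refit
    endog: np.ndarray
    exog: np.ndarray
    offset: np.ndarray | None

    @property
    def crossbasis_coef(self) -> np.ndarray:
        return self.coef[self.crossbasis_index]

    @property
    def crossbasis_vcov(self) -> np.ndarray:
        return self.vcov[np.ix_(self.crossbasis_index, self.crossbasis_index)]


@dataclasses.dataclass(frozen=True)
class RRPrediction:
    """Relative risk versus the centering temperature.

    ``rr_overall`` cumulates the lag contributions over the whole lag
    window (0..L); ``by_lag`` holds the lag-specific curves.  Intervals are
    delta-method 95% bands on the log scale.
    """

    temp_grid: np.ndarray
    rr_overall: np.ndarray
    rr_low: np.ndarray
    rr_high: np.ndarray
    by_lag: np.ndarray
    centering_value: float


def _build_outcome(deaths: np.ndarray, spec: OutcomeSpec):
    """Outcome vector, offset and extra covariate implied by the strategy."""
    offset = None
    extra = None
    if spec.method == "raw" or spec.m == 0:
        y = deaths.copy()
        return y, offset, extra
    Y = build_lag_matrix(deaths, spec.m)
    if spec.method == "sum":
        y = mv_sum(Y)
    elif spec.method == "ar":
        y = mv_ar(Y, spec.ratio)
    elif spec.method in ("pca1", "pca2"):
        y = mv_pca(Y, mode="first" if spec.method == "pca1" else "weighted")
        if np.any(y[np.isfinite(y)] < 0):
            raise PoissonSupportError(
                "PCA-transformed outcome contains negative values and fails "
                "the Poisson support assumption"
            )
    elif spec.method == "adjust":
        y = deaths.copy()
        extra = lag_sum_excluding_current(Y)
    elif spec.method == "offset":
        y = deaths.copy()
        s = lag_sum_excluding_current(Y)
        bad = Y.valid_rows & ~(s > 0)
        if np.any(bad):
            raise ModelFitError(
                "offset strategy requires every lagged-death sum to be "
                f"positive; {int(bad.sum())} rows are not"
            )
        offset = np.where(Y.valid_rows, np.log(np.where(s > 0, s, 1.0)), np.nan)
    else:  # pragma: no cover
        raise ModelFitError(f"unhandled method {spec.method!r}")
    if spec.method in ("sum", "ar", "pca1", "pca2"):
        # transformed outcomes are undefined on incomplete lag windows
        y = np.where(Y.valid_rows, y, np.nan)
    return y, offset, extra


def fit_dlnm(
    data: DailySeries,
    cb: CrossBasis,
    season: SeasonalBasis,
    spec: OutcomeSpec = OutcomeSpec(),
    *,
    include_pollutants: bool = True,
    pvalue_method: str = "wald",
    dispersion: str | float = "pearson",
    maxiter: int = 100,
    tol: float = 1e-8,
) -> FitResult:
    """Fit the Poisson (MV-)DLNM on the jointly valid rows.

    ``cb`` and ``season`` must be built on the same daily calendar as
    ``data`` (see :func:`fit_series` for the one-call version).  Rows enter
    the fit only if the exposure lag window, the outcome construction and
    every covariate are complete there.

    ``dispersion="pearson"`` scales the covariance by the Pearson
    chi-square / df estimate (quasi-Poisson); a float fixes the scale
    (1.0 = plain Poisson).  Point estimates are unaffected either way.
    """
    cal = data.calendar_frame()
    n = len(cal)
    if cb.design.shape[0] != n or season.design.shape[0] != n:
        raise ModelFitError(
            "cross-basis / seasonal basis rows do not match the series calendar"
        )
    deaths = cal["deaths"].to_numpy(dtype=float)
    y, offset, extra = _build_outcome(deaths, spec)

    cols: list[np.ndarray] = [np.ones(n), cb.design]
    names = ["const"] + [
        f"cb_{i}_{j}" for i in range(cb.var_df) for j in range(cb.lag_df)
    ]
    cb_index = np.arange(1, 1 + cb.design.shape[1])
    if include_pollutants:
        cols += [cal["o3"].to_numpy(dtype=float), cal["pm25"].to_numpy(dtype=float)]
        names += ["o3", "pm25"]
    cols.append(season.design)
    names += [f"season_{k}" for k in range(season.df)]
    if extra is not None:
        cols.append(extra)
        names.append("lag_death_sum")
    X = np.column_stack([c if c.ndim == 2 else c[:, None] for c in cols])

    valid = np.isfinite(y) & np.isfinite(X).all(axis=1)
    if offset is not None:
        valid &= np.isfinite(offset)
    n_used = int(valid.sum())
    if n_used == 0:
        raise ModelFitError("no valid rows to fit")
    if n_used < 10 * X.shape[1]:
        warnings.warn(
            f"only {n_used} valid rows for {X.shape[1]} parameters; "
            "estimates may be unstable",
            stacklevel=2,
        )

    yv = y[valid]
    Xv = X[valid]
    off = offset[valid] if offset is not None else None
    if dispersion == "pearson":
        scale_arg: str | float = "X2"
    elif isinstance(dispersion, (int, float)):
        scale_arg = float(dispersion)
    else:
        raise ValueError(f"unknown dispersion setting {dispersion!r}")
    try:
        glm = sm.GLM(yv, Xv, family=sm.families.Poisson(), offset=off)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = glm.fit(maxiter=maxiter, tol=tol, scale=scale_arg)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise ModelFitError(f"IRLS failed: {exc}") from exc

    # log-likelihood at unit scale, so quasi-LR statistics stay comparable
    llf_unit = float(glm.family.loglike(yv, np.asarray(res.mu), scale=1.0))
    fit = FitResult(
        coef=np.asarray(res.params),
        vcov=np.asarray(res.cov_params()),
        names=names,
        crossbasis_index=cb_index,
        overall_p=np.nan,
        converged=bool(res.converged),
        n_used=n_used,
        deviance=float(res.deviance),
        llf=llf_unit,
        deviance_history=list(np.ravel(res.fit_history.get("deviance", []))),
        spec=spec,
        scale=float(res.scale),
        endog=yv,
        exog=Xv,
        offset=off,
    )
    fit.overall_p = overall_pvalue(fit, method=pvalue_method)
    return fit


def fit_series(
    data: DailySeries,
    max_lag: int,
    spec: OutcomeSpec = OutcomeSpec(),
    *,
    centering: float | str = "median",
    season_df: int | None = None,
    season_df_per_year: int = 8,
    include_pollutants: bool = True,
    pvalue_method: str = "wald",
    dispersion: str | float = "pearson",
):
    """Build the lag structure, cross-basis and seasonal spline from a
    series and fit in one call.  Returns ``(fit, cb, season)``."""
    cal = data.calendar_frame()
    lagm = build_lag_matrix(cal["temp"].to_numpy(dtype=float), max_lag)
    cb = build_crossbasis(lagm, centering=centering)
    season = seasonal_basis(
        len(cal), df_per_year=season_df_per_year, total_df=season_df
    )
    fit = fit_dlnm(
        data, cb, season, spec,
        include_pollutants=include_pollutants, pvalue_method=pvalue_method,
        dispersion=dispersion,
    )
    return fit, cb, season


def overall_pvalue(fit: FitResult, method: str = "wald") -> float:
    """Joint test that every cross-basis coefficient is zero.

    ``method="wald"``: W = b' V^{-1} b on the cross-basis block against a
    chi-square with df = block size (rank-adjusted via a generalized
    inverse if the sub-covariance is singular).  ``method="lrt"`` refits
    without the cross-basis columns and compares quasi-deviances (the
    likelihood-ratio statistic is divided by the dispersion estimate).
    """
    idx = fit.crossbasis_index
    if method == "wald":
        b = fit.crossbasis_coef
        V = fit.crossbasis_vcov
        rank = np.linalg.matrix_rank(V)
        if rank == len(idx):
            try:
                W = float(b @ np.linalg.solve(V, b))
            except np.linalg.LinAlgError:
                W = float(b @ pinvh(V) @ b)
        else:
            warnings.warn(
                f"singular cross-basis covariance: rank {rank} < {len(idx)}; "
                "using generalized inverse",
                stacklevel=2,
            )
            W = float(b @ pinvh(V) @ b)
        W = max(W, 0.0)
        return float(stats.chi2.sf(W, df=rank))
    if method == "lrt":
        keep = np.setdiff1d(np.arange(fit.exog.shape[1]), idx)
        glm0 = sm.GLM(
            fit.endog, fit.exog[:, keep],
            family=sm.families.Poisson(), offset=fit.offset,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res0 = glm0.fit(maxiter=100, tol=1e-8, scale=1.0)
        lr = max(2.0 * (fit.llf - float(res0.llf)) / fit.scale, 0.0)
        return float(stats.chi2.sf(lr, df=len(idx)))
    raise ValueError(f"unknown p-value method {method!r}")


def predict_rr(
    fit: FitResult,
    cb: CrossBasis,
    temp_grid=None,
    *,
    conf_level: float = 0.95,
) -> RRPrediction:
    """Relative risk of death at each grid temperature versus the
    centering temperature.

    The overall RR at temperature x is
    ``exp(sum_l [A(x) - A(x0)] . C(l) . beta)`` — the cross-basis contrast
    cumulated over the lag window — with delta-method intervals from the
    coefficient covariance.  Grid values outside the observed boundary are
    extrapolated (with a warning).
    """
    if temp_grid is None:
        lo, hi = cb.var_boundary
        temp_grid = np.arange(np.floor(lo), np.ceil(hi) + 1.0)
    temp_grid = np.atleast_1d(np.asarray(temp_grid, dtype=float))
    lo, hi = cb.var_boundary
    if np.any((temp_grid < lo) | (temp_grid > hi)):
        warnings.warn(
            "prediction grid extends beyond the observed temperature range; "
            "extrapolating the exposure basis",
            stacklevel=2,
        )
    A = cb.exposure_basis(temp_grid)              # g x vx
    A0 = cb.exposure_basis(cb.centering_value)    # 1 x vx
    delta = A - A0
    C = cb.lag_basis                              # (L+1) x vl
    S = C.sum(axis=0)                             # vl

    beta = fit.crossbasis_coef
    V = fit.crossbasis_vcov
    # overall contrast: z[g, i*vl + j] = delta[g, i] * S[j]
    Z = np.einsum("gi,j->gij", delta, S).reshape(len(temp_grid), -1)
    log_rr = Z @ beta
    se = np.sqrt(np.maximum(np.einsum("gk,kl,gl->g", Z, V, Z), 0.0))
    zq = stats.norm.ppf(0.5 + conf_level / 2)
    # lag-specific contrasts: [g, l] = sum_ij delta[g,i] C[l,j] beta[i*vl+j]
    B = beta.reshape(cb.var_df, cb.lag_df)
    by_lag = np.exp(delta @ B @ C.T)
    return RRPrediction(
        temp_grid=temp_grid,
        rr_overall=np.exp(log_rr),
        rr_low=np.exp(log_rr - zq * se),
        rr_high=np.exp(log_rr + zq * se),
        by_lag=by_lag,
        centering_value=cb.centering_value,
    )
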