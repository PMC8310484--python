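"""Permutation type-I-error experiments and Poisson power experiments.

The type-I-error engine permutes the observed death series (breaking any
association with temperature while conserving the count distribution),
rebuilds the lagged-outcome structure from the permuted series, refits the
chosen strategy and records how often the overall cross-basis test rejects
at the 5% level.  A strategy is a valid test only if that proportion stays
at or below the nominal level.

The power engine keeps the observed temperature and pollution structure on
a contiguous study window, draws deaths_t ~ Poisson(lambda = temp_t) so the
association is real, and fits both the conventional DLNM and the
offset-based MV_DLNM, recording each power and how often the MV_DLNM
p-value is strictly the smaller ("wins").
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np

from .data_io import DailySeries, permute_deaths
from .errors import ModelFitError, MVDLNMError
from .lagbasis import build_crossbasis, build_lag_matrix, seasonal_basis
from .model import fit_dlnm
from .transforms import OutcomeSpec

__all__ = ["SimulationSummary", "type1_experiment", "power_experiment",
           "subyear_season_df"]

ALPHA = 0.05


@dataclasses.dataclass(frozen=True)
class SimulationSummary:
    """Rejection / power / wins proportions over simulation replicates.

    Rates are computed over converged replicates; failures are counted
    separately, never silently folded in.  ``se`` is the binomial standard
    error of ``rejection_rate``.
    """

    config: dict
    rejection_rate: float
    n_replicates: int
    n_failed: int
    pvalues: np.ndarray
    wins_rate: float | None = None
    power_reference: float | None = None
    pvalues_reference: np.ndarray | None = None

    @property
    def se(self) -> float:
        n = self.n_replicates - self.n_failed
        if n == 0:
            return float("nan")
        return math.sqrt(self.rejection_rate * (1 - self.rejection_rate) / n)


def subyear_season_df(period_days: int, df_per_year: int = 8) -> int:
    """Seasonal df for a window: ceil(df_per_year * years), floored at 4."""
    return max(4, math.ceil(df_per_year * period_days / 365.25))


def type1_experiment(
    data: DailySeries,
    spec: OutcomeSpec,
    L: int,
    reps: int = 1000,
    seed: int | np.random.Generator | None = None,
    *,
    alpha: float = ALPHA,
    season_df_per_year: int = 8,
    include_pollutants: bool = True,
) -> SimulationSummary:
    """Rejection rate of the overall test under the permutation null.

    Each replicate permutes the death column, rebuilds the strategy's
    outcome/covariate/offset from the permuted series and refits; the
    temperature cross-basis and the seasonal spline design are fixed by
    the (unpermuted) calendar, so they are built once.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cal = data.calendar_frame()
    lagm = build_lag_matrix(cal["temp"].to_numpy(dtype=float), L)
    cb = build_crossbasis(lagm)
    season = seasonal_basis(len(cal), df_per_year=season_df_per_year)

    pvalues = np.full(reps, np.nan)
    n_failed = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(reps):
            perm = permute_deaths(data, rng)
            try:
                fit = fit_dlnm(
                    perm, cb, season, spec,
                    include_pollutants=include_pollutants,
                )
            except MVDLNMError:
                n_failed += 1
                continue
            if not fit.converged:
                n_failed += 1
                continue
            pvalues[r] = fit.overall_p
    ok = np.isfinite(pvalues)
    rate = float(np.mean(pvalues[ok] < alpha)) if ok.any() else float("nan")
    return SimulationSummary(
        config={
            "experiment": "type1", "method": spec.method, "m": spec.m,
            "ratio": spec.ratio, "L": L, "reps": reps, "alpha": alpha,
        },
        rejection_rate=rate,
        n_replicates=reps,
        n_failed=n_failed,
        pvalues=pvalues,
    )


def power_experiment(
    data: DailySeries,
    L: int,
    m: int = 10,
    period_days: int = 365,
    reps: int = 1000,
    seed: int | np.random.Generator | None = None,
    *,
    alpha: float = ALPHA,
    random_start: bool = True,
    include_pollutants: bool = True,
) -> SimulationSummary:
    """Power of MV_DLNM vs the conventional DLNM under a real effect.

    Deaths are drawn Poisson with mean equal to the day's temperature on a
    contiguous window of ``period_days`` (random start per replicate by
    default, so the power estimate is not tied to one season of the year).
    Returns the MV_DLNM rejection rate as ``rejection_rate``, the DLNM's
    as ``power_reference`` and the strict-win proportion as ``wins_rate``.

    Pass the series *before* dropping pollutant-missing days: only the
    temperature must be complete on a window (it is the Poisson mean);
    days with a missing pollutant merely drop out of each fit.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cal = data.calendar_frame()
    n = len(cal)
    if period_days > n:
        raise ValueError(f"period_days={period_days} exceeds series length {n}")
    min_rows = max(L, m) + 10
    if period_days < min_rows:
        raise ValueError(
            f"period_days={period_days} leaves too few rows after a "
            f"{max(L, m)}-day lag window"
        )
    temp_all = cal["temp"].to_numpy(dtype=float)
    if np.nanmin(temp_all) <= 0:
        raise ValueError("temperature must be positive to serve as a Poisson mean")
    season_df = subyear_season_df(period_days)

    p_mv = np.full(reps, np.nan)
    p_raw = np.full(reps, np.nan)
    n_failed = 0
    cb_cache: dict[int, tuple] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(reps):
            start = int(rng.integers(0, n - period_days + 1)) if random_start else 0
            win = cal.iloc[start : start + period_days].copy()
            lam = win["temp"].to_numpy(dtype=float)
            if not np.all(np.isfinite(lam)):
                n_failed += 1
                continue
            win["deaths"] = rng.poisson(lam).astype(float)
            series = DailySeries(win)
            if start not in cb_cache:
                lagm = build_lag_matrix(lam, L)
                cb_cache[start] = (
                    build_crossbasis(lagm),
                    seasonal_basis(period_days, total_df=season_df),
                )
            cb, season = cb_cache[start]
            try:
                fr = fit_dlnm(series, cb, season, OutcomeSpec("raw"),
                              include_pollutants=include_pollutants)
                fm = fit_dlnm(series, cb, season, OutcomeSpec("offset", m=m),
                              include_pollutants=include_pollutants)
            except MVDLNMError:
                n_failed += 1
                continue
            if not (fr.converged and fm.converged):
                n_failed += 1
                continue
            p_raw[r] = fr.overall_p
            p_mv[r] = fm.overall_p
    ok = np.isfinite(p_mv) & np.isfinite(p_raw)
    if ok.any():
        power_mv = float(np.mean(p_mv[ok] < alpha))
        power_raw = float(np.mean(p_raw[ok] < alpha))
        wins = float(np.mean(p_mv[ok] < p_raw[ok]))  # ties count as non-wins
    else:  # pragma: no cover
        power_mv = power_raw = wins = float("nan")
    return SimulationSummary(
        config={
            "experiment": "power", "L": L, "m": m,
            "period_days": period_days, "reps": reps, "alpha": alpha,
            "random_start": random_start, "season_df": season_df,
        },
        rejection_rate=power_mv,
        n_replicates=reps,
        n_failed=n_failed,
        pvalues=p_mv,
        wins_rate=wins,
        power_reference=power_raw,
        pvalues_reference=p_raw,
    )
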