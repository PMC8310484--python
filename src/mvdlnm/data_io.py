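"""Daily environmental mortality series: reading, validation, summaries,
permutation and synthesis.

The central container is :class:`DailySeries`, an immutable wrapper around a
date-indexed DataFrame with four variables: daily mean temperature (degC),
daily mean ozone and PM2.5 concentrations (which may be missing on a few
days), and the daily all-cause death count.  Days dropped because of missing
pollutant readings leave gaps in the index; downstream lag construction
treats a gap as breaking every lag window that crosses it.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataValidationError

__all__ = [
    "DailySeries",
    "SeriesSummary",
    "read_daily_csv",
    "write_daily_csv",
    "describe_series",
    "permute_deaths",
    "generate_synthetic_series",
]

#: canonical variable names, in presentation order
VARIABLES = ("deaths", "temp", "o3", "pm25")


@dataclasses.dataclass(frozen=True)
class DailySeries:
    """Aligned daily records of exposure, confounders and death counts.

    ``frame`` is indexed by a strictly increasing ``DatetimeIndex`` (daily
    resolution, possibly with gaps) and has float columns ``temp``, ``o3``,
    ``pm25`` and ``deaths``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        if not isinstance(f.index, pd.DatetimeIndex):
            raise DataValidationError("DailySeries frame must be date-indexed")
        if len(f) == 0:
            raise DataValidationError("DailySeries is empty")
        if f.index.has_duplicates:
            dup = f.index[f.index.duplicated()][0]
            raise DataValidationError(f"duplicate date in series: {dup.date()}")
        if not f.index.is_monotonic_increasing:
            raise DataValidationError("dates are not sorted")
        missing_cols = [c for c in ("temp", "o3", "pm25", "deaths") if c not in f]
        if missing_cols:
            raise DataValidationError(f"missing columns: {missing_cols}")
        deaths = f["deaths"].to_numpy()
        obs = np.isfinite(deaths)
        if np.any(deaths[obs] < 0) or np.any(deaths[obs] != np.round(deaths[obs])):
            bad = f.index[obs][
                (deaths[obs] < 0) | (deaths[obs] != np.round(deaths[obs]))
            ][0]
            raise DataValidationError(
                f"deaths must be non-negative integers (offending day {bad.date()})"
            )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.frame.index

    @property
    def missing_pollutant_mask(self) -> np.ndarray:
        """Boolean mask of rows flagged for a missing pollutant reading."""
        return self.frame[["o3", "pm25"]].isna().any(axis=1).to_numpy()

    @property
    def n_flagged(self) -> int:
        return int(self.missing_pollutant_mask.sum())

    def drop_missing_pollutants(self) -> "DailySeries":
        """Listwise-drop days with a missing pollutant reading.

        The dropped days leave gaps in the date index, which invalidate any
        lag window that crosses them (see :mod:`mvdlnm.lagbasis`).
        """
        return DailySeries(self.frame.loc[~self.missing_pollutant_mask].copy())

    def calendar_frame(self) -> pd.DataFrame:
        """The series reindexed onto the full daily calendar between its
        first and last day; absent days appear as all-NaN rows."""
        full = pd.date_range(self.frame.index[0], self.frame.index[-1], freq="D")
        return self.frame.reindex(full)

    def window(self, start: int, length: int) -> "DailySeries":
        """A contiguous calendar sub-window (by calendar-day offset)."""
        cal = self.calendar_frame()
        sub = cal.iloc[start : start + length]
        return DailySeries(sub.dropna(how="all"))


@dataclasses.dataclass(frozen=True)
class SeriesSummary:
    """Per-variable descriptive statistics (n, mean, sd, min, max).

    Moments use non-missing values only; ``sd`` is the sample standard
    deviation (n-1 denominator).  A variable with no observed values keeps
    ``n = 0`` and NaN moments.
    """

    table: pd.DataFrame

    def __getitem__(self, variable: str) -> pd.Series:
        return self.table.loc[variable]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.6g")


DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "date": "date",
    "temp": "temp",
    "o3": "o3",
    "pm25": "pm25",
    "deaths": "deaths",
}


def read_daily_csv(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> DailySeries:
    """Read a daily series from a comma-separated file with a header row.

    Parameters
    ----------
    path:
        CSV file with one row per day.
    column_map:
        Maps canonical names (``date``, ``temp``, ``o3``, ``pm25``,
        ``deaths``) to the file's actual header names, so supplementary
        files can be read without renaming columns.

    Rows with a missing pollutant value are kept but flagged; use
    :meth:`DailySeries.drop_missing_pollutants` to filter them.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    path = Path(path)
    if not path.exists():
        raise DataValidationError(f"no such file: {path}")
    raw = pd.read_csv(path)
    missing = [v for v in cmap.values() if v not in raw.columns]
    if missing:
        raise DataValidationError(
            f"columns {missing} not found in {path.name}; have {list(raw.columns)}"
        )
    dates = pd.to_datetime(raw[cmap["date"]], format="ISO8601", errors="coerce")
    if dates.isna().any():
        row = int(np.flatnonzero(dates.isna())[0])
        raise DataValidationError(
            f"unparseable date {raw[cmap['date']].iloc[row]!r} at row {row + 2}"
        )
    frame = pd.DataFrame(
        {
            "temp": pd.to_numeric(raw[cmap["temp"]], errors="coerce").to_numpy(),
            "o3": pd.to_numeric(raw[cmap["o3"]], errors="coerce").to_numpy(),
            "pm25": pd.to_numeric(raw[cmap["pm25"]], errors="coerce").to_numpy(),
            "deaths": pd.to_numeric(raw[cmap["deaths"]], errors="coerce").to_numpy(),
        },
        index=pd.DatetimeIndex(dates.values, name="date"),
    )
    raw_deaths = raw[cmap["deaths"]]
    bad_deaths = frame["deaths"].isna() & raw_deaths.notna().to_numpy()
    if bad_deaths.any():
        row = int(np.flatnonzero(bad_deaths.to_numpy())[0])
        raise DataValidationError(
            f"non-numeric death count {raw_deaths.iloc[row]!r} at row {row + 2}"
        )
    return DailySeries(frame.sort_index())


def write_daily_csv(s: DailySeries, path: str | Path) -> None:
    """Write a series in the same CSV dialect read_daily_csv consumes."""
    out = s.frame.copy()
    out.insert(0, "date", out.index.strftime("%Y-%m-%d"))
    out.to_csv(path, index=False)


def describe_series(s: DailySeries) -> SeriesSummary:
    """n/mean/sd/min/max per variable on non-missing values (sd uses n-1)."""
    rows = {}
    for var in VARIABLES:
        x = s.frame[var].dropna()
        n = len(x)
        rows[var] = {
            "n": n,
            "mean": x.mean() if n else np.nan,
            "sd": x.std(ddof=1) if n > 1 else (0.0 if n == 1 else np.nan),
            "min": x.min() if n else np.nan,
            "max": x.max() if n else np.nan,
        }
    table = pd.DataFrame(rows).T
    table["n"] = table["n"].astype(int)
    return SeriesSummary(table)


def permute_deaths(s: DailySeries, rng: np.random.Generator) -> DailySeries:
    """Uniform random permutation of the death column; every other column —
    and the multiset of counts — is untouched.

    This is the null-generation device of the permutation experiments: the
    permuted deaths keep their marginal distribution but lose all alignment
    with temperature and the calendar.
    """
    frame = s.frame.copy()
    frame["deaths"] = rng.permutation(frame["deaths"].to_numpy())
    return DailySeries(frame)


def generate_synthetic_series(
    n_days: int = 1826,
    effect: float = 0.0,
    rng: np.random.Generator | int | None = None,
    *,
    start: str = "2012-01-01",
    temp_mean: float = 23.6,
    temp_amplitude: float = 6.0,
    temp_ar: float = 0.7,
    temp_resid_sd: float = 3.5,
    deaths_mean: float = 61.4,
    death_season_amplitude: float = 0.13,
    o3_mean: float = 28.0,
    o3_sd: float = 9.6,
    pm25_mean: float = 20.5,
    pm25_sd: float = 10.4,
    o3_missing_rate: float = 0.001,
    pm25_missing_rate: float = 0.009,
    effect_max_lag: int = 10,
    effect_decay: float = 0.7,
) -> DailySeries:
    """Synthesise a Taipei-like daily series.

    Temperature is an annual sinusoid (trough on 1 January) plus AR(1)
    noise; defaults give mean ~23.6 degC and sd ~5.5 degC.  Pollutants are
    positively skewed (lognormal) and weakly correlated with temperature,
    with a dismal missingness rate.  Deaths are Poisson with a smooth
    seasonal log-baseline (winter excess) calibrated to ~61 deaths/day and
    sd ~9.6.

    Parameters
    ----------
    effect:
        Log relative risk per standard deviation of the exponentially
        weighted (ratio ``effect_decay``) average of the current and lagged
        standardised temperatures, over lags ``0..effect_max_lag``.  With
        ``effect=0`` deaths are independent of temperature given the season.
    rng:
        A ``numpy.random.Generator`` or an integer seed.

    Notes
    -----
    Given the same generator state the output is bit-reproducible.
    """
    if n_days < 60:
        raise DataValidationError("n_days must be at least 60")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    t = np.arange(n_days)
    doy = 2 * np.pi * t / 365.25

    # temperature: trough at the start of the calendar year, AR(1) residual
    season_temp = -temp_amplitude * np.cos(doy)
    innov_sd = temp_resid_sd * np.sqrt(1.0 - temp_ar**2)
    eps = rng.normal(0.0, innov_sd, n_days)
    resid = np.empty(n_days)
    resid[0] = rng.normal(0.0, temp_resid_sd)
    for i in range(1, n_days):
        resid[i] = temp_ar * resid[i - 1] + eps[i]
    temp = temp_mean + season_temp + resid
    temp_sd_nominal = np.sqrt(temp_amplitude**2 / 2 + temp_resid_sd**2)
    z_temp = (temp - temp_mean) / temp_sd_nominal

    def _lognormal(mean, sd, z):
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2
        return np.exp(mu + np.sqrt(sigma2) * z)

    # pollutants: right-skewed, weakly tied to the temperature anomaly
    z_o3 = 0.3 * z_temp + np.sqrt(1 - 0.3**2) * rng.standard_normal(n_days)
    z_pm = -0.2 * z_temp + np.sqrt(1 - 0.2**2) * rng.standard_normal(n_days)
    o3 = _lognormal(o3_mean, o3_sd, z_o3)
    pm25 = _lognormal(pm25_mean, pm25_sd, z_pm)
    o3[rng.random(n_days) < o3_missing_rate] = np.nan
    pm25[rng.random(n_days) < pm25_missing_rate] = np.nan

    # deaths: seasonal log-baseline peaking in winter
    log_mu = np.log(deaths_mean) + death_season_amplitude * np.cos(doy)
    if effect != 0.0:
        w = effect_decay ** np.arange(effect_max_lag + 1)
        w /= w.sum()
        padded = np.concatenate([np.zeros(effect_max_lag), z_temp])
        smoothed = np.convolve(padded, w, mode="valid")
        log_mu = log_mu + effect * smoothed
    deaths = rng.poisson(np.exp(log_mu)).astype(float)

    frame = pd.DataFrame(
        {"temp": temp, "o3": o3, "pm25": pm25, "deaths": deaths},
        index=pd.date_range(start, periods=n_days, freq="D", name="date"),
    )
    return DailySeries(frame)
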