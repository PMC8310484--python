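import numpy as np
import pytest

import mvdlnm as mv


@pytest.fixture
def worked_lagm():
    """The 4x3 illustration matrix: 4 days of deaths with two lag days."""
    return mv.build_lag_matrix([62, 51, 60, 73, 61, 55], 2)


@pytest.fixture(scope="session")
def null_series():
    """Five calendar years of synthetic data with no temperature effect,
    pollutant-missing days dropped (the permutation-null test bed)."""
    return mv.generate_synthetic_series(1826, rng=101).drop_missing_pollutants()


@pytest.fixture(scope="session")
def full_series():
    """The same five-year null series before pollutant-missing days are
    dropped — the power engine needs complete temperature."""
    return mv.generate_synthetic_series(1826, rng=101)


@pytest.fixture(scope="session")
def small_series():
    """A short null series for fast model-level tests."""
    return mv.generate_synthetic_series(600, rng=7).drop_missing_pollutants()


@pytest.fixture(scope="session")
def effect_series():
    """Five years with a moderate lagged temperature effect on mortality
    (log-RR 0.1 per SD of smoothed lagged temperature)."""
    return mv.generate_synthetic_series(
        1826, effect=0.1, rng=1
    ).drop_missing_pollutants()


@pytest.fixture(scope="session")
def strong_effect_series():
    """Five years with a strong temperature effect (log-RR 0.15 per SD)."""
    return mv.generate_synthetic_series(
        1826, effect=0.15, rng=1
    ).drop_missing_pollutants()


@pytest.fixture(scope="session")
def small_fit(small_series):
    """One fitted conventional DLNM reused across model tests."""
    fit, cb, season = mv.fit_series(small_series, 5)
    return fit, cb, season


def make_series(deaths, temp=None, start="2015-01-01"):
    """Build a DailySeries from raw arrays (pollutants held benign)."""
    import pandas as pd

    deaths = np.asarray(deaths, dtype=float)
    n = len(deaths)
    if temp is None:
        temp = 20.0 + 5.0 * np.sin(np.arange(n) / 9.0)
    frame = pd.DataFrame(
        {
            "temp": np.asarray(temp, dtype=float),
            "o3": np.full(n, 30.0),
            "pm25": np.full(n, 20.0),
            "deaths": deaths,
        },
        index=pd.date_range(start, periods=n, freq="D", name="date"),
    )
    return mv.DailySeries(frame)
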