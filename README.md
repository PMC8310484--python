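# mvdlnm

Distributed lag non-linear models (DLNMs) for daily temperature–mortality
time series, extended with *lagged-outcome* strategies, and the simulation
machinery (permutation type-I-error and Poisson power studies) that
separates the valid extension from the invalid ones.

## The problem

Environmental epidemiology routinely asks how daily mean temperature — and
its delayed effects over the following days — shapes daily all-cause
mortality, adjusting for air pollution (O₃, PM₂.₅) and season.  The DLNM
answers this with a Poisson regression whose temperature term is a
*cross-basis*: a bidimensional spline surface over temperature and lag,

```
log μ_t = α + s(x_t, l; β) + β_O3·O3_t + β_PM2.5·PM2.5_t + Σᵢ f(z_tⁱ; θ)
```

where `s(x_t, l; β)` couples a quadratic B-spline in temperature (knots at
the 10th/75th/90th percentiles of the observed series) with a natural cubic
spline in lag (5 df, interior knots equally spaced on the log-lag scale,
maximum lag L ∈ {10, 20, 30}), and `f` is a natural cubic spline in the day
index with 8 df per year absorbing season and trend.  The *overall p-value*
tests all cross-basis coefficients jointly; the *overall relative risk*
RR(x) cumulates the fitted temperature contrast over the whole lag window.

The conventional DLNM uses only the current day's deaths as outcome.  This
package also implements five multivariate (MV) strategies that fold the
previous m days' deaths into the model:

| strategy   | construction                                                    |
|------------|-----------------------------------------------------------------|
| `sum`      | outcome = Σ deaths over lags 0..m                               |
| `ar`       | outcome = Σ rᶫ·deaths (geometric ratio r ∈ {0.8, 0.9, 0.98})    |
| `pca1/2`   | outcome = principal-component score of the lagged deaths         |
| `adjust`   | outcome = current deaths, covariate = Σ deaths over lags 1..m   |
| `offset`   | outcome = current deaths, offset = log Σ deaths over lags 1..m  |

Permutation experiments (shuffle the death series, refit, count rejections)
show that the summation/AR/PCA outcomes grossly inflate the type-I error
and that `adjust` inflates moderately, while the offset strategy — the
**MV_DLNM**, which models mortality *rates* instead of counts — keeps the
test valid for lag-outcome depths up to about 10 days and is more powerful
than the conventional DLNM on short study periods.

## Worked example

`examples/` contains one short script per capability.  Fitting a DLNM on a
synthetic five-year series with a known lagged temperature effect
(`examples/01_fit_and_relative_risk.py`) prints

```
rows used: 1548, converged: True
overall p-value of the temperature cross-basis: 1.17e-20
overall RR at 10 degC vs 23.4 degC: 0.81 (95% CI 0.74-0.88)
overall RR at 30 degC vs 23.4 degC: 1.10 (95% CI 1.04-1.16)
```

— the injected effect is detected decisively, and the cumulative relative
risk across the 0–10-day lag window is elevated on hot days (30 °C vs the
23.4 °C median) and reduced on cold days for this generator, whose effect
is monotone in temperature.  The other examples print the five lagged-
outcome transforms on a worked 4×3 matrix, the permutation type-I-error
contrast between strategies, and the power/wins comparison.

A thin CLI mirrors the library:

```bash
mvdlnm synth --days 1826 --seed 7 --out taipei_like.csv
mvdlnm fit --csv taipei_like.csv --max-lag 10 --method offset --m 10 --out-prefix fit
mvdlnm simulate-type1 --csv taipei_like.csv --method offset --m 10 -L 10 \
       --reps 1000 --seed 1 --out type1.tsv
```

## Data

`read_daily_csv` expects a comma-separated file with header columns for
date (ISO-8601), mean temperature (°C), O₃, PM₂.₅ and the daily death
count; a `column_map` binds foreign headers.  Days with a missing pollutant
reading are flagged and dropped listwise; the resulting calendar gaps
invalidate every lag window that crosses them.  `generate_synthetic_series`
emulates a Taipei-like series (≈61 deaths/day, temperature 23.6 ± 5.5 °C,
right-skewed pollutants with a dismal missingness rate) with an optional
lagged temperature effect, and is the test bed for everything below.

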