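# Methods

## Model

For daily death counts μ_t, temperature x_t, pollutants O3_t and PM2.5_t:

```
log μ_t = α + s(x_t, l; β) + β_O3·O3_t + β_PM2.5·PM2.5_t + Σᵢ₌₁..p f(z_tⁱ; θ)
```

`s(x_t, l; β)` is the cross-basis over temperature and lag 0..L: the
row-wise tensor contraction

```
design[t, (i,j)] = Σ_l A_i(x_{t−l}) · C_j(l)
```

of an exposure basis A (quadratic B-spline, three interior knots at the
10th/75th/90th percentiles of the analysed temperatures, boundary knots at
the observed min/max, intercept column dropped → vx = 5) with a lag basis C
(natural cubic spline with intercept, three interior knots equally spaced
on the log-lag scale → vl = 5), giving 25 columns.  Seasonality and trend
are absorbed by one long natural cubic spline in the day index with 8 df
per year (interior knots at equally spaced day-index quantiles, no
intercept); a per-year-blocks variant sits behind the same configuration
surface.  Centering temperature for relative risk defaults to the median
of the analysed series.

The lag-outcome extensions transform the n×(m+1) matrix Y of current and
lagged deaths (depth m is independent of the exposure lag L):
`sum` and `ar` replace the outcome with plain or geometric-ratio-weighted
row sums; `pca1`/`pca2` project the raw rows of Y on covariance
eigenvectors (first, or all weighted by explained variance; signs fixed so
loading sums are positive; scores are not centered — matching the worked
construction — and a correlation-matrix variant sits behind a flag);
`adjust` keeps the current deaths and adds sum(x_sL) = Σ lags 1..m as a
covariate; `offset` (the MV_DLNM) instead offsets by log sum(x_sL),
turning the model into one for mortality rates.  Negative PCA scores are
refused (they leave the Poisson support); a zero lag sum is refused for
the offset model.

## Estimation and inference

Fitting is iteratively reweighted least squares for the Poisson log-link
quasi-likelihood (statsmodels GLM; relative deviance tolerance 1e-8, at
most 100 iterations).  Non-integer transformed outcomes (`sum`/`ar`/`pca`)
are handled by the same scoring equations.  The coefficient covariance is
**quasi-Poisson**: scaled by the Pearson χ²/df dispersion estimate.  Daily
all-cause counts with a seasonal mean are overdispersed relative to
Poisson (the emulated series has marginal variance/mean ≈ 1.5), and once
the permutation null destroys the season–outcome alignment, unscaled
covariance would reject the null for the *conventional* DLNM in roughly
half the replicates — no strategy comparison could be read off such a
base.  With the Pearson scale the conventional DLNM is calibrated
(empirically 0.046–0.048 at 500 replicates) and the published validity
ordering of the strategies emerges.  Pass `dispersion=1.0` for the pure
Poisson covariance.

The overall p-value is a Wald χ² test of the 25 cross-basis coefficients
(W = β̂ᵀV⁻¹β̂, df = block size; a generalized inverse with rank-adjusted df
handles singular blocks, which arise e.g. when L+1 < 5 lag points cannot
support the 5-df lag basis — the basis builder warns about that
configuration).  A quasi-likelihood-ratio variant (scaled by the
dispersion) is available as `overall_pvalue(fit, "lrt")`; the two agree
closely on both null and strong-effect fits.

The overall relative risk at temperature x contrasts the exposure basis at
x against the centering value and cumulates over the lag window:
log RR(x) = Σ_l [A(x) − A(x₀)]·C(l)·β̂, with delta-method 95% intervals
from the scaled covariance; lag-specific curves use the per-lag contrast.
Grid values outside the observed boundary extrapolate the B-spline pieces
with a warning.

### Numerical notes

- Natural cubic splines are built as cubic B-splines projected (QR) onto
  the null space of the boundary second-derivative constraints, with
  first-order Taylor extension beyond the boundary — so they are linear in
  the tails; tests verify span equality with a truncated-power-basis
  construction.
- Rows whose exposure or outcome lag window crosses a missing (dropped)
  day are invalidated, never interpolated; a fit uses only jointly valid
  rows.
- statsmodels' IRLS deviance trace is not monotone in its first step or
  two (opening guess plus step adjustment) and is reported on the
  dispersion-scaled axis; convergence is judged on its tail.
- The fit warns (rather than fails) when valid rows < 10 × parameters:
  short study windows (down to 120 days with L = 20–30) are legitimate
  power-study scenarios despite their thin information.

## Simulation engines

**Type-I error.**  Each replicate permutes the observed death column
uniformly (conserving its multiset), rebuilds the chosen strategy's
outcome/covariate/offset from the permuted series — the temperature
cross-basis and season design are fixed and built once — refits, and
records `overall_p < 0.05`.  Rates are reported over converged replicates
with failures counted separately, plus the binomial standard error.

**Power.**  Each replicate selects a contiguous window of the study series
(random start by default, so the estimate is not tied to one season;
fixed-start mode available), draws deaths_t ~ Poisson(λ = temperature_t),
and fits both the conventional DLNM and the MV_DLNM (offset, default depth
m = 10, the deepest depth the validity study supports).  Reported: each
model's rejection rate and the "wins" fraction where the MV_DLNM p-value
is strictly smaller (ties count as non-wins).  Seasonal df for sub-year
windows scales as max(4, ceil(8 · days/365.25)).  Temperature must be
complete on the series passed in (it is the Poisson mean); days with
missing pollutants merely drop out of each fit.

With a fixed seed both engines are bit-reproducible end to end.

## Synthetic data generator

`generate_synthetic_series` emulates the study conditions: n consecutive
days (default 1826 ≈ five years); temperature = annual sinusoid (amplitude
6 °C, trough at the calendar-year start) + AR(1) noise (ρ = 0.7,
stationary sd 3.5 °C) around 23.6 °C, giving sd ≈ 5.5 °C; lognormal O₃
(mean 28, sd 9.6) and PM₂.₅ (mean 20.5, sd 10.4) weakly correlated with
the temperature anomaly (+0.3 / −0.2 on the latent scale), missing
completely at random at rates 0.1% and 0.9%; deaths Poisson with
log-mean = log 61.4 + 0.13·cos(2πt/365.25) (winter excess calibrated so
the marginal deaths sd ≈ 9.6).  The optional temperature effect adds
`effect` × the exponentially weighted (ratio 0.7) average of the current
and previous 10 days' standardised temperatures to the log-mean; with
`effect = 0`, deaths are independent of temperature given the season.
The amplitude, AR coefficient and decay are configuration choices; only
the first two moments of each variable are calibration targets.

What the generator does **not** emulate: serial correlation of the death
counts beyond the shared seasonal cycle (real mortality series carry
outcome autocorrelation from influenza waves and other slow unmeasured
covariates), heavy cold-tail asymmetry of the temperature distribution,
and pollution episodes.  Consequences for interpretation: permutation
validity and power contrasts transfer well (they are driven by the model
structure), but the real-data amplification of the relative-risk maximum
when lagged outcomes enter the offset depends on genuine outcome
autocorrelation and does not reproduce here — on synthetic data the
offset model's RR is attenuated at shallow depths and only approaches the
count model's RR as the offset smooths out with depth.

## Scenario choices used in tests and the acceptance script

- Validity runs: 500 permutation replicates per configuration on the
  five-year null series; the MV_DLNM validity bound is checked at depths
  m ∈ {1, 4, 7, 10} (L = 10), spanning the monotone inflation direction.
- The significance-depth pattern (non-significant at m = 1, strongly
  significant by m = 4–10 at L = 10) is shown at effect = 0.1 — a
  moderate signal, chosen so the conventional DLNM detects the effect
  while the one-day offset still masks it.
- Power runs: 1-year and 120-day windows, m = 10, 300 replicates in the
  acceptance script (1000 is the reference protocol; the binomial SE at
  300 is ≈ 0.029 at p = 0.5).

## Known limitations

- No penalized smoothing, threshold (hot/cold breakpoint) models,
  overdispersion families beyond the quasi-Poisson scale, or
  attributable-fraction machinery.
- PCA outcomes are fitted only when their support permits; the package
  deliberately refuses to round or shift them.
- The overall p-value construction for the published real-data table is
  not uniquely determined by its source; Wald is the default here, with
  the quasi-LRT behind a flag for sensitivity.
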