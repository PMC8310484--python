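"""The five lagged-outcome (MV) strategies on a tiny worked matrix.

Four days of death counts with two lag days form a 4x3 matrix Y; each
strategy collapses Y to the one-dimensional quantity that enters the
Poisson model as outcome, covariate or offset.

Run:  python examples/02_lagged_outcome_strategies.py
"""

import mvdlnm as mv

deaths = [62, 51, 60, 73, 61, 55]          # six consecutive days
Y = mv.build_lag_matrix(deaths, max_lag=2)  # rows: day t, t-1, t-2
mask = Y.valid_rows
print("lag-outcome matrix Y:")
print(Y.values[mask])

print("MV_sum   (outcome = total over lags 0..2):",
      mv.mv_sum(Y)[mask])
for r in (0.8, 0.9, 0.98):
    print(f"MV_AR    (geometric weights {r}^lag):   ",
          mv.mv_ar(Y, r)[mask])
print("MV_PCA   (first principal-component score):",
      mv.mv_pca(Y, 'first')[mask].round(4))
print("sum(x_sL) (lags 1..2 only — the MV_adjust covariate",
      "and the MV_DLNM offset):", mv.lag_sum_excluding_current(Y)[mask])

# MV_sum/MV_AR replace the outcome with (weighted) cumulative deaths;
# MV_PCA can go negative, which a Poisson outcome cannot; MV_adjust keeps
# the current deaths as outcome and adjusts for sum(x_sL); MV_DLNM instead
# offsets by log(sum(x_sL)), modelling the mortality *rate*.
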