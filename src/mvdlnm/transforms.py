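"""Lagged-outcome (MV) strategies.

Each strategy maps the n x (m+1) matrix of current and lagged death counts
to a one-dimensional quantity that enters the Poisson DLNM as outcome,
covariate or offset:

=========  ==============================================================
method     role of the lagged deaths
=========  ==============================================================
raw        ignored — the conventional DLNM on current deaths
sum        outcome = sum of deaths over lags 0..m
ar         outcome = geometric-ratio weighted sum (weights r**lag)
pca1/pca2  outcome = first / variance-weighted principal-component score
adjust     covariate = sum of deaths over lags 1..m (current kept as outcome)
offset     offset = log of that same sum — the model then describes rates
=========  ==============================================================

All strategies operate row-locally on valid rows; invalid rows stay NaN.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import BasisError
from .lagbasis import LagMatrix

__all__ = [
    "OutcomeSpec",
    "METHODS",
    "mv_sum",
    "mv_ar",
    "mv_pca",
    "lag_sum_excluding_current",
]

METHODS = ("raw", "sum", "ar", "pca1", "pca2", "adjust", "offset")


@dataclasses.dataclass(frozen=True)
class OutcomeSpec:
    """Which lagged-outcome strategy to fit, at what depth.

    Parameters
    ----------
    method:
        One of :data:`METHODS`.  ``raw`` is the conventional DLNM; the
        lag-outcome depth is then irrelevant.
    m:
        Lag-outcome depth in days — independent of the exposure max lag.
    ratio:
        Geometric common ratio in (0, 1] for ``method="ar"``.
    """

    method: str = "raw"
    m: int = 0
    ratio: float = 0.9

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; pick from {METHODS}")
        if self.m < 0:
            raise ValueError("lag-outcome depth m must be >= 0")
        if self.method == "ar" and not (0 < self.ratio <= 1):
            raise ValueError("AR ratio must be in (0, 1]")
        if self.method in ("adjust", "offset", "pca1", "pca2") and self.m < 1:
            raise ValueError(f"method {self.method!r} needs m >= 1")


def mv_sum(Y: LagMatrix) -> np.ndarray:
    """Total deaths from the current day back to the maximal lag day."""
    out = np.full(Y.n, np.nan)
    out[Y.valid_rows] = Y.values[Y.valid_rows].sum(axis=1)
    return out


def mv_ar(Y: LagMatrix, ratio: float) -> np.ndarray:
    """Geometric-ratio weighted sum: the n-day-lag column is weighted
    ``ratio**n``.  ``ratio=1`` recovers :func:`mv_sum`; ratio -> 0 recovers
    the current-day deaths."""
    if ratio <= 0:
        raise ValueError("AR ratio must be positive")
    w = float(ratio) ** np.arange(Y.max_lag + 1)
    out = np.full(Y.n, np.nan)
    out[Y.valid_rows] = Y.values[Y.valid_rows] @ w
    return out


def mv_pca(
    Y: LagMatrix, mode: str = "first", use_correlation: bool = False
) -> np.ndarray:
    """Principal-component score of the lagged-death columns.

    ``mode="first"`` projects the raw rows of Y on the leading eigenvector
    of the column covariance; ``mode="weighted"`` projects on every
    eigenvector and combines the scores with weights proportional to the
    explained variance.  Scores are raw projections (rows are not centered
    first) and eigenvector signs are fixed so each loading sum is positive.

    The result can be negative, which violates the support of a Poisson
    outcome — the model layer detects and refuses that case.
    """
    if mode not in ("first", "weighted"):
        raise ValueError(f"unknown PCA mode {mode!r}")
    if Y.max_lag < 1:
        raise BasisError("PCA needs at least one lag column (m >= 1)")
    Yv = Y.values[Y.valid_rows]
    mat = np.corrcoef(Yv, rowvar=False) if use_correlation else np.cov(Yv, rowvar=False)
    if not np.all(np.isfinite(mat)):
        raise BasisError("degenerate lag-outcome covariance (constant column?)")
    eigval, eigvec = np.linalg.eigh(mat)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if eigval[0] <= 0:
        raise BasisError("degenerate lag-outcome covariance (no positive variance)")
    sign = np.where(eigvec.sum(axis=0) < 0, -1.0, 1.0)
    eigvec = eigvec * sign
    if mode == "first":
        scores = Yv @ eigvec[:, 0]
    else:
        w = np.clip(eigval, 0.0, None)
        w = w / w.sum()
        scores = Yv @ eigvec @ w
    out = np.full(Y.n, np.nan)
    out[Y.valid_rows] = scores
    return out


def lag_sum_excluding_current(Y: LagMatrix) -> np.ndarray:
    """Sum over the m lagged-death columns only (lags 1..m), leaving the
    current day out — the adjust-covariate and the offset numerator."""
    if Y.max_lag < 1:
        raise BasisError("lag sum excluding current needs m >= 1")
    out = np.full(Y.n, np.nan)
    out[Y.valid_rows] = Y.values[Y.valid_rows, 1:].sum(axis=1)
    return out
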