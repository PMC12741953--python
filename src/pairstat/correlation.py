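"""Pearson and Spearman correlation for a single pairwise-complete pair.

Two-sided Pearson p-values come from the symmetric beta distribution with
both shape parameters n/2 - 1 on [-1, 1] (the exact null distribution of r
under bivariate normality); Spearman p-values from the t approximation
t = rho * sqrt((n - 2) / (1 - rho^2)) with n - 2 degrees of freedom.

Degenerate pairs never raise: with at most 1 joint observation neither the
coefficient nor the p-value is defined (NaN); with exactly 2 observations
the coefficient is defined (+-1) but the p-value is not; zero variance in
either vector leaves both undefined.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special

from .data_model import TestResult
from .pairing import PairObservations

__all__ = ["rank_with_ties", "pearson_pair", "spearman_pair"]


def rank_with_ties(values) -> np.ndarray:
    """1-based ranks with tied values sharing the mean of their positions."""
    v = np.asarray(values, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v), dtype=float)
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx <= 0.0 or syy <= 0.0:
        return math.nan
    return float(np.clip(dx @ dy / math.sqrt(sxx * syy), -1.0, 1.0))


def pearson_p(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson r at sample size n (beta CDF)."""
    if n < 3 or math.isnan(r):
        return math.nan
    ab = n / 2.0 - 1.0
    return float(min(1.0, 2.0 * special.betainc(ab, ab, 0.5 * (1.0 - abs(r)))))


def spearman_p(rho: float, n: int) -> float:
    """Two-sided p-value of a Spearman rho at sample size n (t CDF)."""
    if n < 3 or math.isnan(rho):
        return math.nan
    if abs(rho) == 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2.0) / (1.0 - rho * rho))
    return float(min(1.0, 2.0 * special.stdtr(n - 2.0, -abs(t))))


def pearson_pair(obs: PairObservations) -> TestResult:
    """Pearson correlation of one jointly observed pair, with r^2."""
    n = obs.n
    r = _corr(obs.g_vals, obs.h_vals) if n >= 2 else math.nan
    p = pearson_p(r, n)
    r2 = r * r if not math.isnan(r) else math.nan
    return TestResult(statistic=r, p_value=p, effects={"r2": r2}, n_used=n)


def spearman_pair(obs: PairObservations) -> TestResult:
    """Spearman rank correlation of one jointly observed pair.

    rho is the Pearson correlation of tie-averaged ranks, which remains
    valid in the presence of ties (the 6*sum(d^2) shortcut does not).
    """
    n = obs.n
    if n >= 2:
        rho = _corr(rank_with_ties(obs.g_vals), rank_with_ties(obs.h_vals))
    else:
        rho = math.nan
    p = spearman_p(rho, n)
    return TestResult(statistic=rho, p_value=p, effects={"rho": rho}, n_used=n)
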