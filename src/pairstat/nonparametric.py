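"""Mann-Whitney U and Kruskal-Wallis tests on tie-averaged ranks.

The Mann-Whitney test offers three p-value modes:

``asymptotic``
    Normal approximation with the standard tie correction of the variance
    and a 0.5 continuity correction (toggleable).
``exact``
    The exact null distribution of U over all C(n1 + n2, n1) group
    assignments of tie-free data, computed by dynamic programming in exact
    integer arithmetic.
``auto``
    Exact when the pair has no ties after deletion and the smaller group
    has fewer than 8 samples; asymptotic otherwise.

The Kruskal-Wallis H statistic applies the tie correction
C = 1 - sum(t^3 - t) / (n^3 - n) and is referred to the chi-squared
distribution with k - 1 degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import special

from .data_model import TestResult
from .pairing import GroupedSamples
from .correlation import rank_with_ties

__all__ = ["ExactUDistribution", "mwu_exact_distribution", "mwu_pair",
           "kruskal_pair", "EXACT_MAX_PRODUCT"]

#: Largest n1 * n2 for which the exact U distribution is tabulated.
EXACT_MAX_PRODUCT = 5_000_000


@dataclass
class ExactUDistribution:
    """Null distribution of U for group sizes (n1, n2) on tie-free data.

    ``freq[u]`` counts the arrangements of n1 + n2 distinct values giving
    U = u for group 1; the counts are exact integers summing to
    C(n1 + n2, n1) and are symmetric about n1 * n2 / 2.
    """

    n1: int
    n2: int
    freq: list[int]

    @property
    def total(self) -> int:
        return sum(self.freq)

    def cdf(self, u: int) -> float:
        """P(U <= u) as an exactly rounded float ratio of integers."""
        u = min(max(int(u), -1), self.n1 * self.n2)
        return sum(self.freq[: u + 1]) / self.total


@lru_cache(maxsize=256)
def mwu_exact_distribution(n1: int, n2: int,
                           max_product: int = EXACT_MAX_PRODUCT) -> ExactUDistribution:
    """Exact Mann-Whitney U null distribution by dynamic programming.

    U counts, over tie-free data, how many of the n1 * n2 cross-group value
    pairs favour group 1; its null frequencies are the numbers of
    partitions of u into at most n1 parts each at most n2 (the coefficients
    of the Gaussian binomial [n1 + n2 choose n1]_x), accumulated here with
    exact Python integers in O(n1 * n1 * n2) additions.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be positive")
    umax = n1 * n2
    if umax > max_product:
        raise ValueError(
            f"exact distribution for n1*n2 = {umax} exceeds the configured "
            f"bound {max_product}; use the asymptotic mode")
    dp = [0] * (umax + 1)
    dp[0] = 1
    for i in range(1, n1 + 1):
        for u in range(i, umax + 1):  # multiply by 1 / (1 - x^i)
            dp[u] += dp[u - i]
        for u in range(umax, n2 + i - 1, -1):  # multiply by (1 - x^(n2+i))
            dp[u] -= dp[u - (n2 + i)]
    return ExactUDistribution(n1=n1, n2=n2, freq=dp)


def exact_mwu_p(u1: float, n1: int, n2: int) -> float:
    """Two-sided exact p: double the smaller tail, clipped at 1."""
    dist = mwu_exact_distribution(n1, n2)
    u1 = int(round(u1))
    umin = min(u1, n1 * n2 - u1)
    return min(1.0, 2.0 * dist.cdf(umin))


def _mwu_nan(n: int) -> TestResult:
    return TestResult(math.nan, math.nan, {"pearson_r": math.nan}, n)


def mwu_pair(grouped: GroupedSamples, mode: str = "auto",
             continuity: bool = True) -> TestResult:
    """Mann-Whitney U test for a dichotomous grouping of continuous values.

    The reported statistic is U of the first (label-0) group.  The rank
    effect size r = |z| / sqrt(n) is always derived from the asymptotic z,
    even when the p-value itself is exact.  An empty group after pairwise
    deletion leaves everything NaN; requesting the exact mode in the
    presence of ties is an error, since the exact null distribution assumes
    tie-free data.
    """
    if mode not in ("auto", "exact", "asymptotic"):
        raise ValueError("mode must be 'auto', 'exact' or 'asymptotic'")
    if grouped.k != 2 or grouped.lost_category() or any(len(g) == 0 for g in grouped.groups):
        return _mwu_nan(grouped.n)
    g1, g2 = grouped.groups
    n1, n2 = len(g1), len(g2)
    n = n1 + n2
    ranks = rank_with_ties(np.concatenate([g1, g2]))
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1

    _, counts = np.unique(np.concatenate([g1, g2]), return_counts=True)
    tie_term = float((counts.astype(float) ** 3 - counts).sum())
    has_ties = bool((counts > 1).any())

    s2 = (n1 * n2 / 12.0) * ((n + 1) - tie_term / (n * (n - 1)))
    if s2 > 0:
        num = max(u1, u2) - n1 * n2 / 2.0 - (0.5 if continuity else 0.0)
        z = num / math.sqrt(s2)
        p_asym = min(1.0, 2.0 * special.ndtr(-z))
        effect = abs(z) / math.sqrt(n)
    else:
        z = math.nan
        p_asym = math.nan
        effect = math.nan

    if mode == "exact" and has_ties:
        raise ValueError("exact Mann-Whitney p-values are invalid under ties; "
                         "use the asymptotic or auto mode")
    use_exact = mode == "exact" or (
        mode == "auto" and not has_ties and min(n1, n2) < 8)
    p = exact_mwu_p(u1, n1, n2) if use_exact else p_asym
    return TestResult(statistic=float(u1), p_value=p,
                      effects={"pearson_r": effect}, n_used=n)


def kruskal_pair(grouped: GroupedSamples) -> TestResult:
    """Kruskal-Wallis H test with tie correction and eta-squared.

    Degenerate contracts: a vanished category or fewer than 2 observed
    groups yields all NaN; if every value is tied the correction factor is
    zero and H and p are NaN; eta-squared, (H - k + 1) / (n - k), requires
    n > k.
    """
    nan = TestResult(math.nan, math.nan, {"eta2": math.nan}, grouped.n)
    if grouped.lost_category() or grouped.k < 2 or any(len(g) == 0 for g in grouped.groups):
        return nan
    k = grouped.k
    n = grouped.n
    allv = np.concatenate(grouped.groups)
    ranks = rank_with_ties(allv)
    sr = 0.0
    start = 0
    for g in grouped.groups:
        rk = ranks[start:start + len(g)].sum()
        sr += rk * rk / len(g)
        start += len(g)
    _, counts = np.unique(allv, return_counts=True)
    tie_term = float((counts.astype(float) ** 3 - counts).sum())
    c = 1.0 - tie_term / (n ** 3 - n)
    if c <= 0.0:
        return nan
    h = (12.0 / (n * (n + 1)) * sr - 3.0 * (n + 1)) / c
    p = float(special.chdtrc(k - 1, h))
    eta = (h - k + 1) / (n - k) if n > k else math.nan
    return TestResult(statistic=float(h), p_value=p,
                      effects={"eta2": float(eta)}, n_used=n)
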