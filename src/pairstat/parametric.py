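"""Two-sample t-test and one-way ANOVA for grouped continuous values.

Both tests consume a :class:`~pairstat.pairing.GroupedSamples` built from a
(dichotomous or categorical) grouping feature and a continuous feature
after pairwise deletion.  Group variances use the n - 1 denominator.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special

from .data_model import TestResult
from .pairing import GroupedSamples

__all__ = ["ttest_pair", "anova_pair"]

#: Group means within this absolute spread count as "all equal" in the
#: zero-within-variance ANOVA branch.
MEAN_EQUAL_ATOL = 1e-12


def _t_p(t: float, df: float) -> float:
    return float(min(1.0, 2.0 * special.stdtr(df, -abs(t))))


def ttest_pair(grouped: GroupedSamples, variant: str = "student") -> TestResult:
    """Student or Welch two-sample t-test with Cohen's D.

    Degenerate contracts (all-NaN result): fewer than 2 samples in either
    group, fewer than 3 in total, a vanished group, or (Student) a zero
    pooled standard deviation.  For Welch, a zero sum of the two group
    variances leaves Cohen's D (and the zero-denominator t) undefined.
    """
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    nan = TestResult(math.nan, math.nan, {"cohens_d": math.nan}, grouped.n)
    if grouped.k != 2 or grouped.lost_category():
        return nan
    g1, g2 = grouped.groups
    n1, n2 = len(g1), len(g2)
    n = n1 + n2
    if min(n1, n2) < 2 or n < 3:
        return nan
    m1, m2 = g1.mean(), g2.mean()
    v1 = g1.var(ddof=1)
    v2 = g2.var(ddof=1)
    diff = m1 - m2
    if variant == "student":
        df = n - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        if sp2 <= 0.0:
            return nan
        t = diff / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        d = diff / math.sqrt(sp2)
    else:
        se2 = v1 / n1 + v2 / n2
        if se2 <= 0.0:
            return nan
        t = diff / math.sqrt(se2)
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        d = diff / math.sqrt((v1 + v2) / 2.0) if v1 + v2 > 0 else math.nan
    return TestResult(statistic=float(t), p_value=_t_p(t, df),
                      effects={"cohens_d": float(d)}, n_used=n)


def anova_pair(grouped: GroupedSamples) -> TestResult:
    """One-way ANOVA with partial eta-squared.

    When every within-group variance is zero the F ratio degenerates: if the
    group means still differ the statistic is reported as +inf with a zero
    p-value, otherwise everything is NaN.  A vanished category or a single
    observed group also yields the all-NaN marker.
    """
    nan = TestResult(math.nan, math.nan, {"partial_eta2": math.nan}, grouped.n)
    if grouped.lost_category() or grouped.k < 2 or any(len(g) == 0 for g in grouped.groups):
        return nan
    k = grouped.k
    n = grouped.n
    allv = np.concatenate(grouped.groups)
    grand = allv.mean()
    means = np.array([g.mean() for g in grouped.groups])
    sizes = np.array(grouped.sizes, dtype=float)
    ssb = float(sizes @ (means - grand) ** 2)
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(grouped.groups, means)))
    if ssw == 0.0:
        if means.max() - means.min() <= MEAN_EQUAL_ATOL:
            return nan
        return TestResult(statistic=math.inf, p_value=0.0,
                          effects={"partial_eta2": 1.0}, n_used=n)
    f = (ssb / (k - 1)) / (ssw / (n - k))
    p = float(special.fdtrc(k - 1, n - k, f))
    eta = ssb / (ssb + ssw)
    return TestResult(statistic=float(f), p_value=p,
                      effects={"partial_eta2": float(eta)}, n_used=n)
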