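"""Chi-squared test of independence for categorical-categorical pairs.

The contingency table is built over the category labels observed in the
jointly observed subset.  No continuity correction is applied for 2x2
tables: the p-value is defined directly from the survival function of the
chi-squared distribution with (R - 1)(C - 1) degrees of freedom.

Degenerate contracts: if a category present in the full feature disappears
under pairwise deletion, every output is NaN; if one feature has a single
observed category, the statistic and phi are 0 but the p-value and Cramer's
V are undefined (NaN).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special

from .data_model import TestResult
from .pairing import PairObservations

__all__ = ["contingency_table", "chi2_pair"]


def contingency_table(obs: PairObservations):
    """Counts over the observed labels of the two features.

    Returns ``(counts, row_labels, col_labels)`` with ``counts.sum() == n``.
    """
    row_labels, gi = np.unique(obs.g_vals, return_inverse=True)
    col_labels, hi = np.unique(obs.h_vals, return_inverse=True)
    counts = np.zeros((len(row_labels), len(col_labels)), dtype=np.int64)
    np.add.at(counts, (gi, hi), 1)
    return counts, row_labels, col_labels


def _all_nan() -> TestResult:
    return TestResult(math.nan, math.nan,
                      {"phi": math.nan, "cramers_v": math.nan}, 0)


def chi2_pair(obs: PairObservations,
              g_categories: int | None = None,
              h_categories: int | None = None) -> TestResult:
    """Chi-squared independence test for one pair of categorical features.

    ``g_categories``/``h_categories`` give the number of categories present
    in each feature before pairwise deletion; when fewer survive, the result
    is the all-NaN degenerate marker.
    """
    n = obs.n
    if n == 0:
        return _all_nan()
    counts, row_labels, col_labels = contingency_table(obs)
    R, C = counts.shape
    if (g_categories is not None and R < g_categories) or \
       (h_categories is not None and C < h_categories):
        res = _all_nan()
        res.n_used = n
        return res
    rowm = counts.sum(axis=1)
    colm = counts.sum(axis=0)
    expected = np.outer(rowm, colm) / n
    stat = float(((counts - expected) ** 2 / expected).sum())
    dof = (R - 1) * (C - 1)
    p = float(special.chdtrc(dof, stat)) if dof >= 1 else math.nan
    phi = math.sqrt(stat / n)
    mrc = min(R, C)
    v = math.sqrt(stat / (n * (mrc - 1))) if mrc >= 2 else math.nan
    return TestResult(statistic=stat, p_value=p,
                      effects={"phi": phi, "cramers_v": v}, n_used=n)
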