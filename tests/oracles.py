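"""Independent scalar reference implementations used to validate the engine.

Every oracle applies manual pairwise deletion to a feature pair and then
calls the corresponding SciPy routine, exactly mirroring how a careful
analyst would compute one association at a time.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def joint(g: np.ndarray, h: np.ndarray):
    keep = ~(np.isnan(g) | np.isnan(h))
    return g[keep], h[keep]


def groups_of(g: np.ndarray, h: np.ndarray):
    """Continuous values of h split by the labels of g, after deletion."""
    gg, hh = joint(g, h)
    return [hh[gg == lab] for lab in np.unique(gg)]


def scipy_cell(test: str, g: np.ndarray, h: np.ndarray, **opts):
    """(statistic, p) for one feature pair, or None when not computable."""
    gg, hh = joint(g, h)
    n = len(gg)
    if test == "pearson":
        if n < 2 or np.std(gg) == 0 or np.std(hh) == 0:
            return None
        return stats.pearsonr(gg, hh)
    if test == "spearman":
        if n < 3 or np.std(gg) == 0 or np.std(hh) == 0:
            return None
        return stats.spearmanr(gg, hh)
    if test == "chi2":
        if n == 0:
            return None
        table = np.zeros((len(np.unique(gg)), len(np.unique(hh))), dtype=int)
        _, gi = np.unique(gg, return_inverse=True)
        _, hi = np.unique(hh, return_inverse=True)
        np.add.at(table, (gi, hi), 1)
        if table.shape[0] < 2 or table.shape[1] < 2:
            return None
        res = stats.chi2_contingency(table, correction=False)
        return res.statistic, res.pvalue
    groups = [hh[gg == lab] for lab in np.unique(gg)]
    if test == "ttest":
        if len(groups) != 2 or min(map(len, groups)) < 2:
            return None
        return stats.ttest_ind(groups[0], groups[1],
                               equal_var=opts.get("variant", "student") == "student")
    if test == "mwu":
        if len(groups) != 2 or min(map(len, groups)) < 1:
            return None
        x, y = groups
        ties = len(np.unique(np.concatenate(groups))) < n
        mode = opts.get("mode", "auto")
        if mode == "auto":
            mode = "exact" if (not ties and min(len(x), len(y)) < 8) else "asymptotic"
        return stats.mannwhitneyu(x, y, alternative="two-sided", method=mode)
    if test == "anova":
        if len(groups) < 2 or min(map(len, groups)) < 1:
            return None
        return stats.f_oneway(*groups)
    if test == "kruskal":
        if len(groups) < 2 or min(map(len, groups)) < 1:
            return None
        return stats.kruskal(*groups)
    raise ValueError(test)


def mwu_enumerated(n1: int, n2: int):
    """Exact U frequencies by brute-force enumeration of all group
    assignments of n1 + n2 distinct ranks (feasible for n1 + n2 <= 12)."""
    from itertools import combinations
    n = n1 + n2
    freq = [0] * (n1 * n2 + 1)
    for picks in combinations(range(n), n1):
        r1 = sum(picks) + n1  # ranks are 1-based
        u = r1 - n1 * (n1 + 1) // 2
        freq[u] += 1
    return freq


def compare_defined(mine: np.ndarray, idx, oracle_value, collected: list,
                    rtol: float):
    """Record a relative-difference comparison when both sides are defined."""
    m = mine[idx]
    if np.isnan(m) or oracle_value is None or np.isnan(oracle_value):
        return
    denom = max(abs(oracle_value), 1e-300)
    collected.append(abs(m - oracle_value) / denom if abs(oracle_value) > 0
                     else abs(m - oracle_value))
    assert abs(m - oracle_value) <= rtol * max(abs(oracle_value), 1.0), (
        f"cell {idx}: mine={m!r} oracle={oracle_value!r}")
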