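"""Numba kernels for all-pairs statistics with on-the-fly pairwise deletion.

Every kernel walks the sample axis once (or twice, for mean-centred second
passes) per feature pair, skipping entries that are missing (NaN-encoded) in
either feature of the pair.  Kernels return statistic moments and counts;
p-values and effect sizes are attached afterwards with vectorised SciPy
calls, outside nopython code.

Parallelisation is over outer feature rows (one feature per work unit) and
every pair writes only its own output cells, so results are bit-identical
for any thread count.
"""

from __future__ import annotations

import numpy as np
from numba import njit, prange

# ---------------------------------------------------------------------------
# Pearson


@njit(cache=True)
def _pearson_cell(x, y):
    S = x.shape[0]
    n = 0
    sx = 0.0
    sy = 0.0
    for s in range(S):
        xv = x[s]
        yv = y[s]
        if np.isnan(xv) or np.isnan(yv):
            continue
        n += 1
        sx += xv
        sy += yv
    if n == 0:
        return np.nan, 0
    mx = sx / n
    my = sy / n
    sxx = 0.0
    syy = 0.0
    sxy = 0.0
    for s in range(S):
        xv = x[s]
        yv = y[s]
        if np.isnan(xv) or np.isnan(yv):
            continue
        dx = xv - mx
        dy = yv - my
        sxx += dx * dx
        syy += dy * dy
        sxy += dx * dy
    if n < 2 or sxx <= 0.0 or syy <= 0.0:
        return np.nan, n
    r = sxy / np.sqrt(sxx * syy)
    if r > 1.0:
        r = 1.0
    elif r < -1.0:
        r = -1.0
    return r, n


@njit(parallel=True, cache=True)
def pearson_matrix(X):
    F = X.shape[0]
    R = np.full((F, F), np.nan)
    N = np.zeros((F, F), np.int64)
    for i in prange(F):
        for j in range(i, F):
            r, n = _pearson_cell(X[i], X[j])
            R[i, j] = r
            R[j, i] = r
            N[i, j] = n
            N[j, i] = n
    return R, N


# ---------------------------------------------------------------------------
# Spearman


@njit(cache=True)
def _collect_joint(x_other, order_self, idx):
    """Joint-observed sample indices in ascending order of the presorted
    feature; ``order_self`` only lists observed entries of that feature."""
    n = 0
    for k in range(order_self.shape[0]):
        s = order_self[k]
        if s < 0:
            break
        if np.isnan(x_other[s]):
            continue
        idx[n] = s
        n += 1
    return n


@njit(cache=True)
def _avg_rank_fill(x, idx, n, rk):
    """Tie-averaged 1-based ranks of x over idx[:n] (sorted ascending)."""
    i = 0
    while i < n:
        j = i
        v = x[idx[i]]
        while j + 1 < n and x[idx[j + 1]] == v:
            j += 1
        avg = 0.5 * (i + j) + 1.0
        for t in range(i, j + 1):
            rk[idx[t]] = avg
        i = j + 1


@njit(parallel=True, cache=True)
def spearman_matrix(X, order):
    F, S = X.shape
    RHO = np.full((F, F), np.nan)
    N = np.zeros((F, F), np.int64)
    for i in prange(F):
        idx = np.empty(S, np.int64)
        rg = np.empty(S, np.float64)
        rh = np.empty(S, np.float64)
        for j in range(i, F):
            n = _collect_joint(X[j], order[i], idx)
            N[i, j] = n
            N[j, i] = n
            if n < 2:
                continue
            _avg_rank_fill(X[i], idx, n, rg)
            _collect_joint(X[i], order[j], idx)
            _avg_rank_fill(X[j], idx, n, rh)
            m = 0.5 * (n + 1)  # mean rank, exact
            sxx = 0.0
            syy = 0.0
            sxy = 0.0
            for t in range(n):
                s = idx[t]
                dx = rg[s] - m
                dy = rh[s] - m
                sxx += dx * dx
                syy += dy * dy
                sxy += dx * dy
            if sxx <= 0.0 or syy <= 0.0:
                continue
            rho = sxy / np.sqrt(sxx * syy)
            if rho > 1.0:
                rho = 1.0
            elif rho < -1.0:
                rho = -1.0
            RHO[i, j] = rho
            RHO[j, i] = rho
    return RHO, N


# ---------------------------------------------------------------------------
# Chi-squared (categorical x categorical)


@njit(parallel=True, cache=True)
def chi2_matrix(X, present, L):
    """present[f, l]: label l occurs in the full (pre-deletion) feature f.

    A pair is valid only if every such label survives pairwise deletion in
    both features; otherwise all outputs for the pair stay NaN.
    """
    F, S = X.shape
    STAT = np.full((F, F), np.nan)
    N = np.zeros((F, F), np.int64)
    VALID = np.zeros((F, F), np.uint8)
    for i in prange(F):
        table = np.zeros((L + 1, L + 1), np.int64)
        rowm = np.zeros(L + 1, np.int64)
        colm = np.zeros(L + 1, np.int64)
        for j in range(i, F):
            for a in range(L + 1):
                rowm[a] = 0
                colm[a] = 0
                for b in range(L + 1):
                    table[a, b] = 0
            n = 0
            for s in range(S):
                gv = X[i, s]
                hv = X[j, s]
                if np.isnan(gv) or np.isnan(hv):
                    continue
                a = int(gv)
                b = int(hv)
                table[a, b] += 1
                rowm[a] += 1
                colm[b] += 1
                n += 1
            N[i, j] = n
            N[j, i] = n
            ok = n > 0
            for a in range(L + 1):
                if (present[i, a] and rowm[a] == 0) or (present[j, a] and colm[a] == 0):
                    ok = False
            if not ok:
                continue
            stat = 0.0
            for a in range(L + 1):
                if rowm[a] == 0:
                    continue
                for b in range(L + 1):
                    if colm[b] == 0:
                        continue
                    e = rowm[a] * colm[b] / n
                    d = table[a, b] - e
                    stat += d * d / e
            STAT[i, j] = stat
            STAT[j, i] = stat
            VALID[i, j] = 1
            VALID[j, i] = 1
    return STAT, N, VALID


# ---------------------------------------------------------------------------
# Two-sample t moments (dichotomous x continuous)


@njit(parallel=True, cache=True)
def ttest_moments(C, X):
    FC, S = C.shape
    FQ = X.shape[0]
    N1 = np.zeros((FC, FQ), np.int64)
    N2 = np.zeros((FC, FQ), np.int64)
    M1 = np.full((FC, FQ), np.nan)
    M2 = np.full((FC, FQ), np.nan)
    SS1 = np.full((FC, FQ), np.nan)
    SS2 = np.full((FC, FQ), np.nan)
    for a in prange(FC):
        for q in range(FQ):
            n1 = 0
            n2 = 0
            s1 = 0.0
            s2 = 0.0
            for s in range(S):
                cv = C[a, s]
                xv = X[q, s]
                if np.isnan(cv) or np.isnan(xv):
                    continue
                if cv == 0.0:
                    n1 += 1
                    s1 += xv
                else:
                    n2 += 1
                    s2 += xv
            N1[a, q] = n1
            N2[a, q] = n2
            if n1 == 0 and n2 == 0:
                continue
            m1 = s1 / n1 if n1 > 0 else np.nan
            m2 = s2 / n2 if n2 > 0 else np.nan
            ss1 = 0.0
            ss2 = 0.0
            for s in range(S):
                cv = C[a, s]
                xv = X[q, s]
                if np.isnan(cv) or np.isnan(xv):
                    continue
                if cv == 0.0:
                    d = xv - m1
                    ss1 += d * d
                else:
                    d = xv - m2
                    ss2 += d * d
            M1[a, q] = m1
            M2[a, q] = m2
            SS1[a, q] = ss1
            SS2[a, q] = ss2
    return N1, N2, M1, M2, SS1, SS2


# ---------------------------------------------------------------------------
# One-way ANOVA moments (categorical x continuous)


@njit(parallel=True, cache=True)
def anova_moments(C, X, present, L):
    FC, S = C.shape
    FQ = X.shape[0]
    SSB = np.full((FC, FQ), np.nan)
    SSW = np.full((FC, FQ), np.nan)
    N = np.zeros((FC, FQ), np.int64)
    VALID = np.zeros((FC, FQ), np.uint8)
    SPREAD = np.full((FC, FQ), np.nan)  # max - min of group means
    for a in prange(FC):
        cnt = np.zeros(L + 1, np.int64)
        gm = np.zeros(L + 1, np.float64)
        for q in range(FQ):
            for l in range(L + 1):
                cnt[l] = 0
                gm[l] = 0.0
            n = 0
            for s in range(S):
                cv = C[a, s]
                xv = X[q, s]
                if np.isnan(cv) or np.isnan(xv):
                    continue
                l = int(cv)
                cnt[l] += 1
                gm[l] += xv
                n += 1
            ok = n > 0
            for l in range(L + 1):
                if present[a, l] and cnt[l] == 0:
                    ok = False
            if not ok:
                continue
            total = 0.0
            for l in range(L + 1):
                total += gm[l]
            grand = total / n
            ssb = 0.0
            mn = np.inf
            mx = -np.inf
            for l in range(L + 1):
                if cnt[l] > 0:
                    m = gm[l] / cnt[l]
                    gm[l] = m  # reuse as group mean for the second pass
                    d = m - grand
                    ssb += cnt[l] * d * d
                    if m < mn:
                        mn = m
                    if m > mx:
                        mx = m
            ssw = 0.0
            for s in range(S):
                cv = C[a, s]
                xv = X[q, s]
                if np.isnan(cv) or np.isnan(xv):
                    continue
                d = xv - gm[int(cv)]
                ssw += d * d
            N[a, q] = n
            SSB[a, q] = ssb
            SSW[a, q] = ssw
            SPREAD[a, q] = mx - mn
            VALID[a, q] = 1
    return SSB, SSW, N, SPREAD, VALID


# ---------------------------------------------------------------------------
# Mann-Whitney U moments (dichotomous x continuous)


@njit(parallel=True, cache=True)
def mwu_moments(C, X, order):
    """Rank sum of group 0 (R1), group sizes, tie term sum(t^3 - t) and a
    tie flag, per pair.  Uses each continuous feature's precomputed sort
    order: the joint subset is re-ranked in one linear scan."""
    FC, S = C.shape
    FQ = X.shape[0]
    R1 = np.zeros((FC, FQ), np.float64)
    N1 = np.zeros((FC, FQ), np.int64)
    N2 = np.zeros((FC, FQ), np.int64)
    T = np.zeros((FC, FQ), np.float64)
    TIE = np.zeros((FC, FQ), np.uint8)
    for q in prange(FQ):
        for a in range(FC):
            r1 = 0.0
            n1 = 0
            pos = 0
            tsum = 0.0
            tie = False
            run_n = 0
            run_n1 = 0
            run_val = 0.0
            started = False
            for k in range(S):
                s = order[q, k]
                if s < 0:
                    break
                cv = C[a, s]
                if np.isnan(cv):
                    continue
                xv = X[q, s]
                if started and xv == run_val:
                    run_n += 1
                    if cv == 0.0:
                        run_n1 += 1
                else:
                    if started:
                        avg = pos + 0.5 * (run_n + 1)
                        r1 += avg * run_n1
                        if run_n > 1:
                            tie = True
                            tsum += run_n ** 3 - run_n
                        pos += run_n
                        n1 += run_n1
                    run_val = xv
                    run_n = 1
                    run_n1 = 1 if cv == 0.0 else 0
                    started = True
            if started:
                avg = pos + 0.5 * (run_n + 1)
                r1 += avg * run_n1
                if run_n > 1:
                    tie = True
                    tsum += run_n ** 3 - run_n
                pos += run_n
                n1 += run_n1
            R1[a, q] = r1
            N1[a, q] = n1
            N2[a, q] = pos - n1
            T[a, q] = tsum
            TIE[a, q] = 1 if tie else 0
    return R1, N1, N2, T, TIE


# ---------------------------------------------------------------------------
# Kruskal-Wallis moments (categorical x continuous)


@njit(parallel=True, cache=True)
def kruskal_moments(C, X, order, present, L):
    """sum_k R_k^2/n_k over groups, tie term, joint n and validity flag."""
    FC, S = C.shape
    FQ = X.shape[0]
    SR2N = np.full((FC, FQ), np.nan)
    T = np.zeros((FC, FQ), np.float64)
    N = np.zeros((FC, FQ), np.int64)
    VALID = np.zeros((FC, FQ), np.uint8)
    for q in prange(FQ):
        Rk = np.zeros(L + 1, np.float64)
        nk = np.zeros(L + 1, np.int64)
        runc = np.zeros(L + 1, np.int64)
        runlab = np.empty(L + 1, np.int64)
        for a in range(FC):
            for l in range(L + 1):
                Rk[l] = 0.0
                nk[l] = 0
            pos = 0
            tsum = 0.0
            run_n = 0
            run_nlab = 0
            run_val = 0.0
            started = False
            for k in range(S):
                s = order[q, k]
                if s < 0:
                    break
                cv = C[a, s]
                if np.isnan(cv):
                    continue
                xv = X[q, s]
                l = int(cv)
                if started and xv == run_val:
                    run_n += 1
                    if runc[l] == 0:
                        runlab[run_nlab] = l
                        run_nlab += 1
                    runc[l] += 1
                else:
                    if started:
                        avg = pos + 0.5 * (run_n + 1)
                        for t in range(run_nlab):
                            ll = runlab[t]
                            Rk[ll] += avg * runc[ll]
                            nk[ll] += runc[ll]
                            runc[ll] = 0
                        if run_n > 1:
                            tsum += run_n ** 3 - run_n
                        pos += run_n
                    run_val = xv
                    run_n = 1
                    run_nlab = 1
                    runlab[0] = l
                    runc[l] = 1
                    started = True
            if started:
                avg = pos + 0.5 * (run_n + 1)
                for t in range(run_nlab):
                    ll = runlab[t]
                    Rk[ll] += avg * runc[ll]
                    nk[ll] += runc[ll]
                    runc[ll] = 0
                if run_n > 1:
                    tsum += run_n ** 3 - run_n
                pos += run_n
            n = pos
            ok = n > 0
            for l in range(L + 1):
                if present[a, l] and nk[l] == 0:
                    ok = False
            N[a, q] = n
            T[a, q] = tsum
            if not ok:
                continue
            sr = 0.0
            for l in range(L + 1):
                if nk[l] > 0:
                    sr += Rk[l] * Rk[l] / nk[l]
            SR2N[a, q] = sr
            VALID[a, q] = 1
    return SR2N, T, N, VALID
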