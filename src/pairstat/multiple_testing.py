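"""Bonferroni, Benjamini-Hochberg and Benjamini-Yekutieli adjustment.

Adjusted p-values are reported (no accept/reject decisions).  NaN entries —
degenerate pairs whose test was never actually performed — stay NaN and do
not count towards the number of tests m.  For a homogeneous (square,
symmetric) p-value matrix, each unordered off-diagonal pair counts once;
the self-test diagonal is excluded and forced to NaN in the output.
"""

from __future__ import annotations

import numpy as np

__all__ = ["METHODS", "adjust_pvalues", "adjust_matrix"]

METHODS = ("bonferroni", "benjamini_hochberg", "benjamini_yekutieli")

_ALIASES = {"bh": "benjamini_hochberg", "by": "benjamini_yekutieli",
            "fdr_bh": "benjamini_hochberg", "fdr_by": "benjamini_yekutieli"}


def _canonical(method: str) -> str:
    method = _ALIASES.get(method.lower(), method.lower())
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return method


def adjust_pvalues(p, method: str) -> np.ndarray:
    """Adjust a vector of p-values; NaNs pass through and are excluded from m."""
    method = _canonical(method)
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("adjust_pvalues expects a 1-D vector")
    defined = ~np.isnan(p)
    q = p[defined]
    if ((q < 0) | (q > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    m = q.size
    if m == 0:
        return out
    if method == "bonferroni":
        adj = np.minimum(q * m, 1.0)
    else:
        order = np.argsort(q, kind="stable")
        scaled = q[order] * m / np.arange(1, m + 1)
        if method == "benjamini_yekutieli":
            scaled *= (1.0 / np.arange(1, m + 1)).sum()
        # step-up: enforce monotonicity from the largest p downwards
        adj_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
        adj = np.empty(m)
        adj[order] = adj_sorted
    out[defined] = adj
    return out


def adjust_matrix(P, homogeneous: bool, method: str) -> np.ndarray:
    """Adjust a p-value matrix.

    Homogeneous matrices are treated as one hypothesis per unordered
    off-diagonal pair: the upper triangle is adjusted as a vector, mirrored
    back symmetrically, and the diagonal set to NaN.  Mixed matrices are
    adjusted over all defined cells with the shape preserved.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2:
        raise ValueError("adjust_matrix expects a 2-D matrix")
    if homogeneous:
        if P.shape[0] != P.shape[1]:
            raise ValueError("homogeneous p-value matrices must be square")
        iu = np.triu_indices(P.shape[0], k=1)
        adj = adjust_pvalues(P[iu], method)
        out = np.full(P.shape, np.nan)
        out[iu] = adj
        out[(iu[1], iu[0])] = adj
        return out
    return adjust_pvalues(P.ravel(), method).reshape(P.shape)
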