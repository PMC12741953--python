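"""All-pairs test execution: pair enumeration, scheduling, bundle assembly.

Seven tests are registered here, one per combination of variable kinds:

==============  ============================  =========================
name            input kinds                   statistic / effect sizes
==============  ============================  =========================
pearson         continuous (one matrix)       r / r^2
spearman        continuous (one matrix)       rho / rho
chi2            categorical (one matrix)      chi^2 / phi, Cramer's V
ttest           dichotomous x continuous      t / Cohen's D
mwu             dichotomous x continuous      U / rank r = |z|/sqrt(n)
anova           categorical x continuous      F / partial eta^2
kruskal         categorical x continuous      H / eta^2
==============  ============================  =========================

Homogeneous tests fill a symmetric F x F matrix, computing each unordered
pair once; the diagonal carries the self-test value for statistics and
unadjusted p-values, and is NaN in any multiple-testing-adjusted matrix.
Mixed tests fill an F_C x F_Q matrix (grouping features on rows).

Missing values are removed per pair, inside the compute kernels, never as a
global preprocessing step; results are independent of the thread count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import special

from . import _kernels
from .data_model import MixedMatrix, ResultBundle
from .multiple_testing import adjust_matrix
from .nonparametric import exact_mwu_p
from .pairing import (GroupedSamples, PairObservations, SortedFeature,
                      group_by_label, joint_observed, presort_features)

__all__ = ["TestDef", "TESTS", "run_pairwise", "available_tests",
           "joint_observed", "presort_features", "PairObservations",
           "SortedFeature", "GroupedSamples", "group_by_label"]

ADJUSTED_NAMES = {"p_bonferroni": "bonferroni",
                  "p_benjamini_hochberg": "benjamini_hochberg",
                  "p_benjamini_yekutieli": "benjamini_yekutieli"}

DEFAULT_OUTPUTS = ("statistic", "p_unadjusted")

#: Guard for the per-pair contingency / per-group scratch arrays, which are
#: sized by the largest category label in the matrix.
MAX_LABEL = 10_000


@dataclass(frozen=True)
class TestDef:
    name: str
    homogeneous: bool
    a_kinds: tuple[str, ...]
    b_kinds: tuple[str, ...] | None
    effect_names: tuple[str, ...]
    runner: Callable

    @property
    def output_names(self) -> tuple[str, ...]:
        return (("statistic", "p_unadjusted") + tuple(ADJUSTED_NAMES) +
                self.effect_names + ("n_used",))


def _order_matrix(X: np.ndarray) -> np.ndarray:
    """Per-feature ascending sample order of non-missing values, -1 padded."""
    F, S = X.shape
    order = np.full((F, S), -1, dtype=np.int64)
    for f in range(F):
        obs = np.flatnonzero(~np.isnan(X[f]))
        order[f, :obs.size] = obs[np.argsort(X[f, obs], kind="stable")]
    return order


def _category_presence(C: np.ndarray):
    """Per-feature presence mask over labels 0..L and full category counts."""
    finite = C[~np.isnan(C)]
    L = int(finite.max()) if finite.size else 0
    if L > MAX_LABEL:
        raise ValueError(f"largest category label {L} exceeds the supported "
                         f"maximum {MAX_LABEL}")
    present = np.zeros((C.shape[0], L + 1), dtype=bool)
    for f in range(C.shape[0]):
        row = C[f][~np.isnan(C[f])]
        if row.size:
            present[f, np.unique(row).astype(np.int64)] = True
    return present, present.sum(axis=1).astype(np.int64), L


def _two_sided_t(t: np.ndarray, df: np.ndarray, mask: np.ndarray) -> np.ndarray:
    p = np.full(t.shape, np.nan)
    if mask.any():
        p[mask] = np.minimum(1.0, 2.0 * special.stdtr(df[mask], -np.abs(t[mask])))
    return p


# ---------------------------------------------------------------------------
# runners: kernel moments -> full output matrices


def _run_pearson(A: MixedMatrix, B, opts) -> dict:
    X = A.values_with_nan()
    R, N = _kernels.pearson_matrix(X)
    p = np.full(R.shape, np.nan)
    mask = (N >= 3) & np.isfinite(R)
    if mask.any():
        ab = N[mask] / 2.0 - 1.0
        p[mask] = np.minimum(1.0, 2.0 * special.betainc(ab, ab, 0.5 * (1.0 - np.abs(R[mask]))))
    return {"statistic": R, "p_unadjusted": p, "r2": R ** 2, "n_used": N}


def _run_spearman(A: MixedMatrix, B, opts) -> dict:
    X = A.values_with_nan()
    RHO, N = _kernels.spearman_matrix(X, _order_matrix(X))
    mask = (N >= 3) & np.isfinite(RHO)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = RHO * np.sqrt((N - 2.0) / (1.0 - RHO ** 2))
    t = np.where(np.abs(RHO) == 1.0, np.inf, t)
    p = _two_sided_t(t, np.maximum(N - 2.0, 1e-300), mask)
    return {"statistic": RHO, "p_unadjusted": p, "rho": RHO.copy(), "n_used": N}


def _run_chi2(A: MixedMatrix, B, opts) -> dict:
    X = A.values_with_nan()
    present, cnt, L = _category_presence(X)
    STAT, N, VALID = _kernels.chi2_matrix(X, present, L)
    R = cnt[:, None].astype(float)
    C = cnt[None, :].astype(float)
    dof = (R - 1.0) * (C - 1.0)
    valid = VALID.astype(bool)
    p = np.full(STAT.shape, np.nan)
    m = valid & (dof >= 1)
    if m.any():
        p[m] = special.chdtrc(dof[m], STAT[m])
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(valid & (N > 0), np.sqrt(STAT / N), np.nan)
        minrc = np.minimum(R, C)
        v = np.where(valid & (minrc >= 2) & (N > 0),
                     np.sqrt(STAT / (N * np.maximum(minrc - 1.0, 1e-300))), np.nan)
    return {"statistic": STAT, "p_unadjusted": p, "phi": phi,
            "cramers_v": v, "n_used": N}


def _run_ttest(A: MixedMatrix, B: MixedMatrix, opts) -> dict:
    variant = opts.get("variant", "student")
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    C = A.values_with_nan()
    X = B.values_with_nan()
    N1, N2, M1, M2, SS1, SS2 = _kernels.ttest_moments(C, X)
    n = N1 + N2
    defined = (np.minimum(N1, N2) >= 2) & (n >= 3)
    t = np.full(n.shape, np.nan)
    df = np.full(n.shape, np.nan)
    d = np.full(n.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        v1 = SS1 / np.maximum(N1 - 1, 1)
        v2 = SS2 / np.maximum(N2 - 1, 1)
        diff = M1 - M2
        if variant == "student":
            sp2 = (SS1 + SS2) / np.maximum(n - 2, 1)
            ok = defined & (sp2 > 0)
            t[ok] = diff[ok] / np.sqrt(sp2[ok] * (1.0 / N1[ok] + 1.0 / N2[ok]))
            df[ok] = n[ok] - 2.0
            d[ok] = diff[ok] / np.sqrt(sp2[ok])
        else:
            se2 = v1 / N1 + v2 / N2
            ok = defined & (se2 > 0)
            t[ok] = diff[ok] / np.sqrt(se2[ok])
            df[ok] = se2[ok] ** 2 / ((v1[ok] / N1[ok]) ** 2 / (N1[ok] - 1.0)
                                     + (v2[ok] / N2[ok]) ** 2 / (N2[ok] - 1.0))
            vsum = v1 + v2
            dm = ok & (vsum > 0)
            d[dm] = diff[dm] / np.sqrt(vsum[dm] / 2.0)
    p = _two_sided_t(t, df, ok)
    return {"statistic": t, "p_unadjusted": p, "cohens_d": d, "n_used": n}


def _run_anova(A: MixedMatrix, B: MixedMatrix, opts) -> dict:
    C = A.values_with_nan()
    X = B.values_with_nan()
    present, cnt, L = _category_presence(C)
    SSB, SSW, N, SPREAD, VALID = _kernels.anova_moments(C, X, present, L)
    K = np.broadcast_to(cnt[:, None].astype(float), N.shape)
    valid = VALID.astype(bool) & (K >= 2)
    f = np.full(N.shape, np.nan)
    p = np.full(N.shape, np.nan)
    eta = np.full(N.shape, np.nan)
    from .parametric import MEAN_EQUAL_ATOL
    blowup = valid & (SSW == 0) & (SPREAD > MEAN_EQUAL_ATOL)
    f[blowup] = np.inf
    p[blowup] = 0.0
    eta[blowup] = 1.0
    ok = valid & (SSW > 0) & (N - K >= 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f[ok] = (SSB[ok] / (K[ok] - 1.0)) / (SSW[ok] / (N[ok] - K[ok]))
        eta[ok] = SSB[ok] / (SSB[ok] + SSW[ok])
    if ok.any():
        p[ok] = special.fdtrc(K[ok] - 1.0, N[ok] - K[ok], f[ok])
    return {"statistic": f, "p_unadjusted": p, "partial_eta2": eta, "n_used": N}


def _run_mwu(A: MixedMatrix, B: MixedMatrix, opts) -> dict:
    mode = opts.get("mode", "auto")
    continuity = opts.get("continuity", True)
    if mode not in ("auto", "exact", "asymptotic"):
        raise ValueError("mode must be 'auto', 'exact' or 'asymptotic'")
    C = A.values_with_nan()
    X = B.values_with_nan()
    R1, N1, N2, T, TIE = _kernels.mwu_moments(C, X, _order_matrix(X))
    n = N1 + N2
    valid = (N1 >= 1) & (N2 >= 1)
    U1 = np.where(valid, R1 - N1 * (N1 + 1) / 2.0, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = (N1 * N2 / 12.0) * ((n + 1.0) - T / np.maximum(n * (n - 1.0), 1e-300))
    sd = np.sqrt(np.maximum(s2, 0.0))
    zok = valid & (sd > 0)
    z = np.full(n.shape, np.nan)
    num = np.maximum(U1, N1 * N2 - U1) - N1 * N2 / 2.0 - (0.5 if continuity else 0.0)
    z[zok] = num[zok] / sd[zok]
    p = np.full(n.shape, np.nan)
    p[zok] = np.minimum(1.0, 2.0 * special.ndtr(-z[zok]))
    effect = np.full(n.shape, np.nan)
    effect[zok] = np.abs(z[zok]) / np.sqrt(n[zok])
    if mode == "exact" and bool((valid & (TIE == 1)).any()):
        raise ValueError("exact Mann-Whitney p-values are invalid under ties; "
                         "use the asymptotic or auto mode")
    if mode != "asymptotic":
        exact_cells = valid & (TIE == 0)
        if mode == "auto":
            exact_cells &= np.minimum(N1, N2) < 8
        for a, q in zip(*np.nonzero(exact_cells)):
            p[a, q] = exact_mwu_p(U1[a, q], int(N1[a, q]), int(N2[a, q]))
    return {"statistic": U1, "p_unadjusted": p, "pearson_r": effect, "n_used": n}


def _run_kruskal(A: MixedMatrix, B: MixedMatrix, opts) -> dict:
    C = A.values_with_nan()
    X = B.values_with_nan()
    present, cnt, L = _category_presence(C)
    SR2N, T, N, VALID = _kernels.kruskal_moments(C, X, _order_matrix(X), present, L)
    K = np.broadcast_to(cnt[:, None].astype(float), N.shape)
    valid = VALID.astype(bool) & (K >= 2)
    h = np.full(N.shape, np.nan)
    p = np.full(N.shape, np.nan)
    eta = np.full(N.shape, np.nan)
    Nf = N.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ctie = 1.0 - T / np.maximum(Nf ** 3 - Nf, 1e-300)
        h0 = 12.0 / np.maximum(Nf * (Nf + 1.0), 1e-300) * SR2N - 3.0 * (Nf + 1.0)
    ok = valid & (ctie > 0)
    h[ok] = h0[ok] / ctie[ok]
    if ok.any():
        p[ok] = special.chdtrc(K[ok] - 1.0, np.maximum(h[ok], 0.0))
    em = ok & (Nf > K)
    eta[em] = (h[em] - K[em] + 1.0) / (Nf[em] - K[em])
    return {"statistic": h, "p_unadjusted": p, "eta2": eta, "n_used": N}


TESTS: dict[str, TestDef] = {
    "pearson": TestDef("pearson", True, ("continuous",), None, ("r2",), _run_pearson),
    "spearman": TestDef("spearman", True, ("continuous",), None, ("rho",), _run_spearman),
    "chi2": TestDef("chi2", True, ("categorical", "dichotomous"), None,
                    ("phi", "cramers_v"), _run_chi2),
    "ttest": TestDef("ttest", False, ("dichotomous",), ("continuous",),
                     ("cohens_d",), _run_ttest),
    "mwu": TestDef("mwu", False, ("dichotomous",), ("continuous",),
                   ("pearson_r",), _run_mwu),
    "anova": TestDef("anova", False, ("categorical", "dichotomous"), ("continuous",),
                     ("partial_eta2",), _run_anova),
    "kruskal": TestDef("kruskal", False, ("categorical", "dichotomous"), ("continuous",),
                       ("eta2",), _run_kruskal),
}


def available_tests() -> tuple[str, ...]:
    return tuple(TESTS)


def _set_threads(threads: int) -> None:
    import numba
    if threads < 1:
        raise ValueError("threads must be a positive integer")
    numba.set_num_threads(min(int(threads), numba.config.NUMBA_NUM_THREADS))


def run_pairwise(test, A: MixedMatrix, B: MixedMatrix | None = None,
                 threads: int = 1, requested_outputs=None, **options) -> ResultBundle:
    """Run one test over all feature pairs and assemble a result bundle.

    Parameters
    ----------
    test:
        Registered test name (see :func:`available_tests`) or a
        :class:`TestDef`.
    A, B:
        Validated matrices.  Homogeneous tests take a single matrix;
        mixed tests take the grouping matrix as ``A`` and the continuous
        matrix as ``B``, sharing the sample dimension.
    threads:
        Worker thread count.  Results are identical for every value.
    requested_outputs:
        Names of result matrices to return (default: statistic and
        unadjusted p).  Adjusted p-value matrices are named
        ``p_bonferroni``, ``p_benjamini_hochberg``, ``p_benjamini_yekutieli``.
    options:
        Test-specific options (``variant`` for ttest; ``mode`` and
        ``continuity`` for mwu).
    """
    tdef = TESTS[test] if isinstance(test, str) else test
    if A.kind not in tdef.a_kinds:
        raise ValueError(f"test {tdef.name!r} requires a {'/'.join(tdef.a_kinds)} "
                         f"matrix, got {A.kind!r}")
    if tdef.b_kinds is None:
        if B is not None:
            raise ValueError(f"test {tdef.name!r} takes a single input matrix")
    else:
        if B is None:
            raise ValueError(f"test {tdef.name!r} requires a second, "
                             f"{'/'.join(tdef.b_kinds)} matrix")
        if B.kind not in tdef.b_kinds:
            raise ValueError(f"second matrix for {tdef.name!r} must be "
                             f"{'/'.join(tdef.b_kinds)}, got {B.kind!r}")
        if A.n_samples != B.n_samples:
            raise ValueError("input matrices must share the sample dimension "
                             f"({A.n_samples} != {B.n_samples})")

    requested = tuple(requested_outputs) if requested_outputs else DEFAULT_OUTPUTS
    bad = [name for name in requested if name not in tdef.output_names]
    if bad:
        raise ValueError(f"invalid output(s) {bad} for test {tdef.name!r}; "
                         f"valid names: {sorted(tdef.output_names)}")

    _set_threads(threads)
    matrices = tdef.runner(A, B, options)
    for name, method in ADJUSTED_NAMES.items():
        if name in requested:
            matrices[name] = adjust_matrix(matrices["p_unadjusted"],
                                           homogeneous=tdef.homogeneous,
                                           method=method)
    row_names = A.feature_names
    col_names = A.feature_names if tdef.homogeneous else (B.feature_names if B else None)
    return ResultBundle(
        matrices={name: matrices[name] for name in requested},
        test=tdef.name, homogeneous=tdef.homogeneous,
        row_names=row_names, col_names=col_names,
        meta={"threads": threads, "options": dict(options),
              "n_samples": A.n_samples},
    )
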