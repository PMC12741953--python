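"""Synthetic mixed-type cohort matrices with controlled missingness.

Continuous features are i.i.d. uniform on [0, 1]; categorical features are
label-encoded with every one of the ``c`` categories guaranteed to appear
at least once per feature (before missingness is injected); dichotomous
features are the 2-category special case.

Missingness mechanisms:

MCAR
    Exactly ``round(miss_rate * S)`` entries per feature, at positions
    drawn uniformly without replacement, independent of all values.
MAR
    Per-entry Bernoulli missingness with probability
    ``sigmoid(a + slope * z_s)``, where ``z`` is a fully observed driver —
    by default an auxiliary standard-uniform covariate drawn alongside the
    matrix, or a designated feature (which is then left fully observed).
    The intercept ``a`` is solved numerically so the expected missing
    fraction equals ``miss_rate``.
MNAR
    Same logistic form, but driven by the entry's own (standardised)
    value, so larger values are more likely to go missing.

All draws descend from a single seed through NumPy's SeedSequence
spawning, one stream per feature, so matrices are bit-reproducible and
independent of any parallelism downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .data_model import MixedMatrix, validate_matrix

__all__ = ["SimSpec", "simulate_matrix", "inject_missing", "simulate_dataset"]

MECHANISMS = ("MCAR", "MAR", "MNAR")


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one simulated matrix."""

    F: int
    S: int
    kind: str = "continuous"
    c: int = 4
    miss_rate: float = 0.1
    mechanism: str = "MCAR"
    na_value: float = float("nan")
    seed: int = 0
    mar_slope: float = 3.0
    driver_feature: int | None = None

    def __post_init__(self):
        if self.F < 1 or self.S < 1:
            raise ValueError("F and S must be positive")
        if self.kind not in ("continuous", "dichotomous", "categorical"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if not 0.0 <= self.miss_rate < 1.0:
            raise ValueError("miss_rate must lie in [0, 1)")
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}")
        c = 2 if self.kind == "dichotomous" else self.c
        if self.kind != "continuous":
            if c < 2:
                raise ValueError("categorical features need at least 2 categories")
            if self.S < c:
                raise ValueError("each category must appear at least once: need S >= c")
            if self.S - round(self.miss_rate * self.S) < c:
                raise ValueError("miss_rate leaves fewer observed entries than categories")

    @property
    def n_categories(self) -> int:
        return 2 if self.kind == "dichotomous" else self.c


_STREAMS = {"values": 1, "missing": 2, "driver": 3}


def _feature_rngs(seed: int, count: int, stream: str) -> list[np.random.Generator]:
    root = np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],))
    return [np.random.Generator(np.random.PCG64(child)) for child in root.spawn(count)]


def simulate_matrix(spec: SimSpec) -> MixedMatrix:
    """Generate a complete (no missing entries) matrix for ``spec``."""
    rngs = _feature_rngs(spec.seed, spec.F, "values")
    if spec.kind == "continuous":
        values = np.stack([rng.uniform(0.0, 1.0, spec.S) for rng in rngs])
    else:
        c = spec.n_categories
        rows = []
        for rng in rngs:
            row = rng.integers(0, c, spec.S).astype(float)
            # guarantee every category at least once per feature
            pos = rng.choice(spec.S, size=c, replace=False)
            row[pos] = rng.permutation(c)
            rows.append(row)
        values = np.stack(rows)
    return validate_matrix(values, kind=spec.kind, na_value=spec.na_value)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _solve_intercept(driver: np.ndarray, slope: float, rate: float) -> float:
    """Intercept a with mean(sigmoid(a + slope * driver)) == rate."""
    def gap(a):
        return _sigmoid(a + slope * driver).mean() - rate
    return optimize.brentq(gap, -50.0, 50.0)


def _standardise(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def inject_missing(M: MixedMatrix, spec: SimSpec) -> MixedMatrix:
    """Return a copy of ``M`` with missingness injected per ``spec``.

    ``M`` must be fully observed.  Every feature is guaranteed to retain at
    least one observed entry.
    """
    if M.missing_mask().any():
        raise ValueError("inject_missing expects a fully observed matrix")
    F, S = M.values.shape
    values = M.values.copy()
    if spec.miss_rate == 0.0:
        return MixedMatrix(values, M.kind, M.na_value, M.feature_names, M.sample_names)
    k = round(spec.miss_rate * S)
    rngs = _feature_rngs(spec.seed, F, "missing")

    if spec.mechanism == "MAR":
        if spec.driver_feature is not None:
            driver = _standardise(values[spec.driver_feature])
        else:
            aux_rng = _feature_rngs(spec.seed, 1, "driver")[0]
            driver = _standardise(aux_rng.uniform(0.0, 1.0, S))

    for f in range(F):
        rng = rngs[f]
        if spec.mechanism == "MCAR":
            if k == 0:
                continue
            pos = rng.permutation(S)[:k]
            mask = np.zeros(S, dtype=bool)
            mask[pos] = True
        else:
            if spec.mechanism == "MAR":
                if spec.driver_feature is not None and f == spec.driver_feature:
                    continue  # the designated driver stays fully observed
                z = driver
            else:  # MNAR: driven by the entry's own value
                z = _standardise(values[f])
            a = _solve_intercept(z, spec.mar_slope, spec.miss_rate)
            mask = rng.uniform(0.0, 1.0, S) < _sigmoid(a + spec.mar_slope * z)
        if mask.all():
            mask[rng.integers(0, S)] = False
        values[f, mask] = spec.na_value
    return MixedMatrix(values, M.kind, M.na_value, M.feature_names, M.sample_names)


def simulate_dataset(spec: SimSpec) -> MixedMatrix:
    """Convenience: generate a matrix and inject missingness in one call."""
    return inject_missing(simulate_matrix(spec), spec)
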