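"""Matrix containers and validation shared by all pairwise tests.

The central object is :class:`MixedMatrix`, a feature-by-sample matrix of
floats in which one of three variable kinds is declared for every feature
(continuous, dichotomous, or categorical) and missing entries are marked by
a user-chosen floating-point sentinel (NaN by default).  Categorical and
dichotomous features are label-encoded: every non-missing entry is a
non-negative integer-valued float, with dichotomous features restricted to
the labels {0, 1}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "KINDS",
    "MixedMatrix",
    "TestResult",
    "ResultBundle",
    "ValidationError",
    "is_missing",
    "validate_matrix",
]

KINDS = ("continuous", "dichotomous", "categorical")


class ValidationError(ValueError):
    """Raised when an input matrix violates the declared variable kind."""


def is_missing(x, na_value):
    """Elementwise missingness test.

    An entry is missing iff the sentinel is NaN and the entry is NaN, or the
    entry equals a finite sentinel exactly.
    """
    x = np.asarray(x, dtype=float)
    if isinstance(na_value, float) and math.isnan(na_value):
        return np.isnan(x)
    return x == na_value


@dataclass
class MixedMatrix:
    """An oriented feature-by-sample matrix with a declared variable kind.

    ``values`` always has features on the rows and samples on the columns
    (shape ``(F, S)``), regardless of the orientation of the raw input it
    was validated from.
    """

    values: np.ndarray
    kind: str
    na_value: float = float("nan")
    feature_names: list[str] | None = None
    sample_names: list[str] | None = None

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean F-by-S mask, True where the entry is missing."""
        return is_missing(self.values, self.na_value)

    def values_with_nan(self) -> np.ndarray:
        """A float64 copy in which missing entries are NaN.

        This is the canonical internal encoding consumed by the compute
        kernels; for a NaN sentinel it is simply a copy.
        """
        out = np.array(self.values, dtype=np.float64, copy=True)
        if not (isinstance(self.na_value, float) and math.isnan(self.na_value)):
            out[out == self.na_value] = np.nan
        return out


@dataclass
class TestResult:
    """Statistic, two-sided p-value and effect size(s) for one feature pair.

    Any field may be NaN when the corresponding quantity is undefined for
    the jointly observed data (the per-test degenerate contracts).
    """

    statistic: float
    p_value: float
    effects: Mapping[str, float]
    n_used: int

    def __post_init__(self):
        p = self.p_value
        if not (math.isnan(p) or 0.0 <= p <= 1.0):
            raise ValueError(f"p_value must be NaN or in [0, 1], got {p!r}")


@dataclass
class ResultBundle:
    """Named collection of feature-by-feature result matrices.

    For homogeneous tests every matrix is F-by-F and symmetric (up to NaN);
    for mixed tests rows index the categorical/dichotomous features and
    columns the continuous ones.
    """

    matrices: dict[str, np.ndarray]
    test: str
    homogeneous: bool
    row_names: list[str] | None = None
    col_names: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.matrices[name]

    def __contains__(self, name: str) -> bool:
        return name in self.matrices

    def keys(self):
        return self.matrices.keys()

    def items(self):
        return self.matrices.items()


def _as_float_2d(raw) -> np.ndarray:
    arr = np.asarray(raw, dtype=np.float64)
    if arr.ndim != 2:
        raise ValidationError(f"input must be 2-dimensional, got {arr.ndim} dimension(s)")
    if arr.shape[0] == 0 or arr.shape[1] == 0:
        raise ValidationError(f"input must have at least 1 feature and 1 sample, got shape {arr.shape}")
    return arr


def validate_matrix(
    raw,
    kind: str,
    na_value: float = float("nan"),
    feature_axis: str = "rows",
    feature_names: Sequence[str] | None = None,
    sample_names: Sequence[str] | None = None,
) -> MixedMatrix:
    """Orient and validate a raw numeric matrix into a :class:`MixedMatrix`.

    Parameters
    ----------
    raw:
        Two-dimensional numeric array-like.
    kind:
        One of ``continuous``, ``dichotomous``, ``categorical``.
    na_value:
        Floating-point sentinel marking missing entries (NaN allowed).
    feature_axis:
        ``"rows"`` (default) if features index the rows of ``raw``,
        ``"columns"`` if they index the columns (the matrix is transposed).

    Raises
    ------
    ValidationError
        For non-2-D input, an empty dimension, label-encoding violations in
        categorical/dichotomous matrices (negative, non-integral, or, for
        dichotomous, outside {0, 1}), or NaN entries alongside a finite
        sentinel.
    """
    if kind not in KINDS:
        raise ValidationError(f"unknown kind {kind!r}; expected one of {KINDS}")
    if feature_axis not in ("rows", "columns"):
        raise ValidationError("feature_axis must be 'rows' or 'columns'")

    values = _as_float_2d(raw)
    if feature_axis == "columns":
        values = values.T
    values = np.ascontiguousarray(values)

    na_value = float(na_value)
    na_is_nan = math.isnan(na_value)
    if not na_is_nan and np.isnan(values).any():
        f, s = np.argwhere(np.isnan(values))[0]
        raise ValidationError(
            f"NaN entry at feature {f}, sample {s} but the missing-value sentinel "
            f"is finite ({na_value}); use a NaN sentinel or recode the entry"
        )

    if kind in ("dichotomous", "categorical"):
        observed = ~is_missing(values, na_value)
        vals = values[observed]
        bad = (vals < 0) | (vals != np.floor(vals))
        if kind == "dichotomous":
            bad |= vals > 1
        if bad.any():
            rows = np.nonzero(observed)[0][bad]
            label = "dichotomous (labels must be 0 or 1)" if kind == "dichotomous" else (
                "categorical (labels must be non-negative integers)")
            raise ValidationError(
                f"feature {rows[0]} contains an invalid {label} entry"
            )

    fnames = list(feature_names) if feature_names is not None else None
    snames = list(sample_names) if sample_names is not None else None
    if fnames is not None and len(fnames) != values.shape[0]:
        raise ValidationError("feature_names length does not match feature count")
    if snames is not None and len(snames) != values.shape[1]:
        raise ValidationError("sample_names length does not match sample count")

    return MixedMatrix(values=values, kind=kind, na_value=na_value,
                       feature_names=fnames, sample_names=snames)
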