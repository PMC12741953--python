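"""Pairwise-complete extraction primitives.

For each feature pair (g, h) the engine restricts to the jointly observed
samples — those positions where neither feature is missing — and feeds only
these to the statistical test.  This is pairwise deletion: no sample is
discarded globally, only per pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import MixedMatrix, is_missing

__all__ = ["PairObservations", "SortedFeature", "GroupedSamples",
           "joint_observed", "presort_features", "group_by_label"]


@dataclass
class PairObservations:
    """Jointly observed sample values for one feature pair."""

    g_vals: np.ndarray
    h_vals: np.ndarray

    @property
    def n(self) -> int:
        return len(self.g_vals)


@dataclass
class SortedFeature:
    """Ascending sort order of one feature's non-missing values.

    ``order`` holds the sample indices of the non-missing entries, sorted so
    that the values are non-decreasing; ``ranks_source`` holds those sorted
    values (used downstream for tie detection during subset re-ranking).
    """

    order: np.ndarray
    ranks_source: np.ndarray


def joint_observed(g, h, na_value=float("nan")) -> PairObservations:
    """Extract the pairwise-complete observations of two feature vectors.

    Returns the paired entries where both values are non-missing, in the
    original sample order.  The result may be empty.
    """
    g = np.asarray(g, dtype=float)
    h = np.asarray(h, dtype=float)
    if g.shape != h.shape or g.ndim != 1:
        raise ValueError(f"feature vectors must be 1-D of equal length, got {g.shape} and {h.shape}")
    keep = ~(is_missing(g, na_value) | is_missing(h, na_value))
    return PairObservations(g_vals=g[keep], h_vals=h[keep])


def presort_features(A: MixedMatrix) -> list[SortedFeature]:
    """Sort every continuous feature once, for reuse across all its pairs.

    Rank-based tests re-rank the jointly observed subset of a pair in a
    single linear scan of this precomputed order instead of re-sorting per
    pair.
    """
    if A.kind != "continuous":
        raise ValueError("presorting applies to continuous matrices")
    out = []
    X = A.values_with_nan()
    for row in X:
        obs = np.flatnonzero(~np.isnan(row))
        order = obs[np.argsort(row[obs], kind="stable")]
        out.append(SortedFeature(order=order, ranks_source=row[order]))
    return out


@dataclass
class GroupedSamples:
    """Continuous values split by the observed labels of a grouping feature.

    Groups are ordered by ascending label.  ``expected_categories`` is the
    number of categories present in the grouping feature before pairwise
    deletion; tests treat a pair in which one of these categories vanished
    as degenerate.
    """

    labels: np.ndarray
    groups: list[np.ndarray]
    expected_categories: int | None = None

    @property
    def n(self) -> int:
        return sum(len(g) for g in self.groups)

    @property
    def k(self) -> int:
        return len(self.groups)

    @property
    def sizes(self) -> list[int]:
        return [len(g) for g in self.groups]

    def lost_category(self) -> bool:
        return self.expected_categories is not None and self.k < self.expected_categories


def group_by_label(obs: PairObservations, expected_categories: int | None = None) -> GroupedSamples:
    """Split a (grouping, continuous) observation pair into per-label groups."""
    labels = np.unique(obs.g_vals)
    groups = [obs.h_vals[obs.g_vals == lab] for lab in labels]
    return GroupedSamples(labels=labels, groups=groups,
                          expected_categories=expected_categories)
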