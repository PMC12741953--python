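from __future__ import annotations

import numpy as np
import pytest

import pairstat as ps


def make_continuous(F, S, miss, seed):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.0, 1.0, (F, S))
    if miss > 0:
        X[rng.uniform(0, 1, X.shape) < miss] = np.nan
    return ps.validate_matrix(X, "continuous")


def make_categorical(F, S, miss, seed, c=3):
    rng = np.random.default_rng(seed)
    X = rng.integers(0, c, (F, S)).astype(float)
    if miss > 0:
        X[rng.uniform(0, 1, X.shape) < miss] = np.nan
    return ps.validate_matrix(X, "categorical")


def make_dichotomous(F, S, miss, seed):
    return ps.MixedMatrix(make_categorical(F, S, miss, seed, c=2).values,
                          "dichotomous")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def obs(g, h):
    return ps.joint_observed(np.asarray(g, float), np.asarray(h, float))


def grouped(groups, expected=None):
    """Build GroupedSamples directly from per-label value lists."""
    labels = np.arange(len(groups), dtype=float)
    return ps.GroupedSamples(labels=labels,
                             groups=[np.asarray(g, float) for g in groups],
                             expected_categories=expected)
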