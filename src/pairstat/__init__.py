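"""pairstat: all-pairs statistical association testing for mixed-type
feature-by-sample matrices with on-the-fly pairwise missing-data removal.

Seven tests cover every combination of continuous, dichotomous and
categorical features (Pearson, Spearman, chi-squared, t-test, Mann-Whitney
U, one-way ANOVA, Kruskal-Wallis), each returning matrices of statistics,
two-sided p-values, multiple-testing-corrected p-values and effect sizes.

>>> import pairstat as ps
>>> spec = ps.SimSpec(F=20, S=200, miss_rate=0.1, seed=7)
>>> data = ps.simulate_dataset(spec)
>>> bundle = ps.pearson(data, requested_outputs=["statistic", "p_unadjusted",
...                                              "p_benjamini_hochberg"])
>>> bundle["statistic"].shape
(20, 20)
"""

from __future__ import annotations

from .data_model import (KINDS, MixedMatrix, ResultBundle, TestResult,
                         ValidationError, is_missing, validate_matrix)
from .pairing import (GroupedSamples, PairObservations, SortedFeature,
                      group_by_label, joint_observed, presort_features)
from .correlation import pearson_pair, rank_with_ties, spearman_pair
from .contingency import chi2_pair, contingency_table
from .parametric import anova_pair, ttest_pair
from .nonparametric import (ExactUDistribution, kruskal_pair,
                            mwu_exact_distribution, mwu_pair)
from .multiple_testing import METHODS, adjust_matrix, adjust_pvalues
from .engine import TESTS, available_tests, run_pairwise
from .simulate import SimSpec, inject_missing, simulate_dataset, simulate_matrix
from .io import read_matrix, write_bundle, write_matrix

__version__ = "0.1.0"


def _homogeneous(test):
    def run(data: MixedMatrix, threads: int = 1, requested_outputs=None, **options):
        return run_pairwise(test, data, None, threads=threads,
                            requested_outputs=requested_outputs, **options)
    run.__name__ = test
    run.__doc__ = f"Run the {test} test on all feature pairs of one matrix."
    return run


def _mixed(test):
    def run(groups: MixedMatrix, values: MixedMatrix, threads: int = 1,
            requested_outputs=None, **options):
        return run_pairwise(test, groups, values, threads=threads,
                            requested_outputs=requested_outputs, **options)
    run.__name__ = test
    run.__doc__ = (f"Run the {test} test for every (grouping, continuous) "
                   "feature pair of two matrices sharing the sample axis.")
    return run


pearson = _homogeneous("pearson")
spearman = _homogeneous("spearman")
chi2 = _homogeneous("chi2")
ttest = _mixed("ttest")
mwu = _mixed("mwu")
anova = _mixed("anova")
kruskal = _mixed("kruskal")

__all__ = [
    "KINDS", "METHODS", "TESTS", "MixedMatrix", "ResultBundle", "TestResult",
    "ValidationError", "PairObservations", "SortedFeature", "GroupedSamples",
    "ExactUDistribution", "SimSpec",
    "validate_matrix", "is_missing", "joint_observed", "presort_features",
    "group_by_label", "rank_with_ties", "pearson_pair", "spearman_pair",
    "chi2_pair", "contingency_table", "ttest_pair", "anova_pair", "mwu_pair",
    "mwu_exact_distribution", "kruskal_pair", "adjust_pvalues", "adjust_matrix",
    "run_pairwise", "available_tests", "simulate_matrix", "inject_missing",
    "simulate_dataset", "read_matrix", "write_matrix", "write_bundle",
    "pearson", "spearman", "chi2", "ttest", "mwu", "anova", "kruskal",
    "__version__",
]
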