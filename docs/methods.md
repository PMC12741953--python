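# Methods

## Pairwise deletion model

All computations operate on an oriented matrix `X ∈ ℝ^{F×S}` (features ×
samples) with a declared variable kind per matrix and a floating-point
missing-value sentinel (NaN by default; a finite sentinel is matched by
exact equality, and NaN entries are rejected at validation time when the
sentinel is finite, so missingness is always unambiguous). For each
feature pair the statistic is computed from the jointly observed sample
set `I(g, h)`; this set is formed inside the compute kernel for that pair,
never by globally dropping samples. The per-pair sample count `n = |I|`
therefore varies across cells of the result matrix, and each cell's
degrees of freedom follow its own `n`.

Categorical variables are label-encoded integers `0..c−1` stored as
floats; a dichotomous variable is the 2-category case restricted to labels
{0, 1}. The "category set" of a feature is the set of labels observed in
the full feature; tests that group by category treat the disappearance of
any such label under pairwise deletion as a degenerate pair (NaN outputs),
so degrees of freedom based on category counts are unambiguous whenever a
result is defined.

## Per-test definitions and degenerate contracts

**Pearson.** Two-sided p from the exact null of r under bivariate
normality: with `a = b = n/2 − 1`, `p = 2·B_cdf((1 − |r|)/2; a, b)`.
`n ≤ 1`: r, r², p undefined; `n = 2`: r = ±1 defined, p undefined (needs
`n ≥ 3` for positive beta shapes); zero variance in either vector: r and p
undefined.

**Spearman.** ρ is the Pearson correlation of tie-averaged ranks (the
`6Σd²` shortcut is invalid under ties). p from
`t = ρ·sqrt((n−2)/(1−ρ²))` with `n − 2` df; `|ρ| = 1 → p = 0`. Same
degeneracy thresholds as Pearson. In the engine, each feature is sorted
once; the joint subset of a pair is re-ranked in a single linear scan of
that order, and equality of this path with from-scratch ranking is
asserted in tests.

**Chi-squared.** `χ² = Σ (O − E)²/E` over the contingency table of
observed labels, `E` from the margins, df `(R−1)(C−1)`, no continuity
correction for 2×2 tables (an explicit design choice: the p-value is
defined directly through the χ² survival function). Effects:
`φ = sqrt(χ²/n)` (reported for all table shapes) and Cramér's
`V = sqrt(χ²/(n·(min(R,C)−1)))`. An emptied pre-deletion category → all
NaN; a single-category feature → p and V NaN (χ² and φ are then 0).

**t-test.** Student: pooled variance, df `n−2`; Welch: unpooled, with
Welch–Satterthwaite df. Cohen's D uses the pooled SD (Student) or
`sqrt((s₁²+s₂²)/2)` (Welch) — the latter is the only denominator
consistent with treating a zero variance *sum* as the undefined case.
Degenerate: `min(n₁,n₂) < 2` or `n < 3` or zero pooled SD (Student) → all
NaN. For Welch with both variances zero the t denominator is itself zero,
so t and p are reported NaN along with D.

**One-way ANOVA.** `F = (SS_B/(k−1))/(SS_W/(n−k))`, partial
`η² = SS_B/(SS_B+SS_W)`. If all within-group variances are zero the ratio
degenerates: when the group means still differ, F = +inf with p = 0 (and
partial η² = 1); when they coincide, everything is NaN. "Means equal" is
decided at absolute tolerance 1e-12 — group means rather than group sums,
since F depends on means and sums would conflate unequal group sizes.

**Mann–Whitney U.** `U₁ = R₁ − n₁(n₁+1)/2` from tie-averaged joint ranks
(reported for the label-0 group). Asymptotic mode:
`σ² = (n₁n₂/12)·((n+1) − ΣT/(n(n−1)))` with `T = Σ(t³−t)` over tie groups,
`z = (max(U₁,U₂) − n₁n₂/2 − ½)/σ` (continuity correction on by default,
toggleable), `p = min(1, 2·Φ̄(z))`. Exact mode: p = `min(1, 2·P(U ≤
min(U₁,U₂)))` from the exact distribution below; requesting it under ties
is an error. Auto: exact iff the pair is tie-free and `min(n₁,n₂) < 8`.
The rank-biserial-style effect `r = |z|/√n` always comes from the
asymptotic z, even when p is exact; its sign is dropped. All values tied
(σ = 0) → p and r NaN; an empty group → all NaN.

**Exact U distribution.** The null frequencies of U for sizes (n₁, n₂)
are the numbers of partitions of u into at most n₁ parts each ≤ n₂
(equivalently the coefficients of the Gaussian binomial
`[n₁+n₂ choose n₁]_x`). They are accumulated with exact Python integers by
the bounded-partition recurrence — multiply the running polynomial by
`1/(1−x^i)` and `(1−x^{n₂+i})` for `i = 1..n₁` — which is algebraically
identical to the classical two-index counting recurrence
`f(n₁,n₂,u) = f(n₁−1,n₂,u−n₂) + f(n₁,n₂−1,u)` but needs only `O(n₁·n₂)`
memory, so it also covers the auto-mode case of one small and one large
group. Exact integers matter: the counts exceed 2⁵³ already around
n = 60, where float accumulation would silently round. A configured bound
on `n₁·n₂` (default 5·10⁶) guards against accidental huge tabulations and
points the user to the asymptotic mode.

**Kruskal–Wallis.** `H = [12/(n(n+1))·Σ R_k²/n_k − 3(n+1)] / C` with tie
correction `C = 1 − ΣT/(n³−n)`; p from χ² with `k−1` df;
`η² = (H − k + 1)/(n − k)`, undefined when `n ≤ k`. All values tied
(C = 0) → H and p NaN; emptied category or `k < 2` → all NaN.

## Multiple testing

Bonferroni, Benjamini–Hochberg (step-up with enforced monotonicity) and
Benjamini–Yekutieli (BH inflated by `Σ 1/i`) are implemented directly;
NaN p-values — tests that were never actually performed — are excluded
from the test count `m` and pass through as NaN. For homogeneous result
matrices each unordered off-diagonal pair counts once (each association is
one hypothesis); the self-test diagonal is excluded from `m` and forced to
NaN in adjusted matrices, while statistic and unadjusted-p matrices carry
the computed self-test values (r = 1, p = 0, …). statsmodels serves as an
independent oracle in the tests, never as the implementation.

## Engine and parallelism

Statistics are computed by numba-compiled kernels parallelised over outer
feature rows (one feature per work unit, so a continuous feature's sort
order is reused across all its pairs). P-values and effect sizes are then
attached by vectorised SciPy special-function calls
(`betainc`, `stdtr`, `chdtrc`, `fdtrc`, `ndtr`) on whole matrices —
distribution evaluations are not reimplemented. Each pair writes only its
own output cells and there are no cross-thread reductions, so bundles are
bit-identical for every thread count; a request for more threads than the
process supports is clamped. Homogeneous tests compute each unordered pair
once and mirror. Mean-centred two-pass accumulation is used wherever a
variance or covariance is formed, keeping agreement with scalar reference
implementations near machine precision (the test suite asserts 1e-9
relative agreement for parametric tests and 1e-8 for rank tests against
SciPy after manual per-pair deletion).

## Simulator

The generator emulates benchmark-style cohort matrices: continuous
features i.i.d. uniform on [0, 1]; categorical features uniform over
`c` labels (default c = 4) with each label forced to appear at least once
per feature *before* missingness injection (a random permutation of all
labels is written to c random positions). Missingness:

- **MCAR** removes exactly `round(rate·S)` entries per feature at
  uniformly drawn positions (default rate 0.1, the typical benchmark
  setting).
- **MAR** draws per-entry Bernoulli missingness with probability
  `sigmoid(a + s·z)` where `z` is a fully observed standardised driver and
  the intercept `a` is solved by root-finding so the expected missing
  fraction equals the target. The driver is by default an auxiliary
  uniform covariate generated alongside the matrix — so every feature can
  be thinned at the target rate — or, if a feature index is designated,
  that feature's own values (the designated feature is then left fully
  observed). Slope default s = 3, strong enough that MNAR visibly biases
  observed means while keeping per-entry probabilities well inside (0, 1).
- **MNAR** uses the same logistic form driven by each entry's own
  standardised value, so larger values go missing more often.

Every feature retains at least one observed entry. All draws descend from
a single seed through `SeedSequence` spawning with fixed stream keys, one
generator per feature, so matrices are bit-reproducible and independent of
downstream parallelism.

What the simulator does *not* model: correlated feature structure,
realistic cohort marginals (age distributions, assay detection limits), or
block-structured missingness from skipped questionnaires. Tests passing on
these matrices therefore establish numerical and contractual correctness
of the engine — not that any particular real cohort satisfies the tests'
statistical assumptions.

## Problem sizes and numerical choices

The test suite validates cell-level correctness on 15×40 matrices at 0%,
10% and 50% missingness (large enough to hit degenerate cells at high
missingness, small enough for exhaustive scalar cross-checking), thread
invariance on 200×500, and end-to-end capability on a 1,000×1,000
continuous matrix with 10% missingness, which completes in a few seconds
on one CPU. Ties in rank tests are exercised by rounding simulated values.
Correlations are clipped to [−1, 1] after the covariance ratio;
`p` values are clipped to [0, 1] after doubling one-sided tails.

## Known limitations

Only the seven listed tests; no covariate adjustment, one-sided
alternatives, paired designs or post-hoc tests. Scratch arrays for
category-grouped kernels are sized by the largest label, so labels should
be compact (a guard rejects labels above 10,000). Memory for the result
bundles is `O(F²)` per requested output. Single-machine, shared-memory
parallelism only.
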