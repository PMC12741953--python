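"""The exact Mann-Whitney U null distribution for small samples.

For two tie-free groups of sizes 3 and 4 the exact two-sided p-value is
computed from the full null distribution of U (counted by dynamic
programming over all C(7, 3) = 35 group assignments) and compared with the
normal approximation, which is unreliable at these sizes.
"""

import numpy as np

import pairstat as ps

dist = ps.mwu_exact_distribution(3, 4)
print(f"U frequencies for n1=3, n2=4: {dist.freq}  (total {dist.total})")

g = ps.GroupedSamples(labels=np.array([0.0, 1.0]),
                      groups=[np.array([1.2, 2.5, 3.1]),
                              np.array([2.9, 4.0, 5.5, 6.1])])
exact = ps.mwu_pair(g, mode="exact")
asym = ps.mwu_pair(g, mode="asymptotic")
auto = ps.mwu_pair(g, mode="auto")
print(f"U = {exact.statistic:.0f}")
print(f"exact p      = {exact.p_value:.4f}")
print(f"asymptotic p = {asym.p_value:.4f}")
print(f"auto mode picks the exact p here ({auto.p_value:.4f}) because both")
print("groups are tie-free and the smaller one has fewer than 8 samples")
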