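"""Exact Mann-Whitney comparison of normalized expression in two groups.

Simulates a 7-vs-7 comparison in which the disease group carries a true
two-fold reduction of the target, normalizes to EAR, and tests the group
difference with the exact two-tailed Mann-Whitney U (skewed expression
data rarely justify a t-test).
"""

import numpy as np

from earnorm import box_summary, mann_whitney_exact

rng = np.random.default_rng(1)
control = 2.0 ** rng.normal(0.0, 0.4, 7)     # normalized target levels
disease = 2.0 ** rng.normal(-1.0, 0.4, 7)    # true 2-fold reduction

res = mann_whitney_exact(control, disease)
print(f"U = {res.statistic:.1f}, two-sided p = {res.p_value:.4f} "
      f"({res.method}, n1={res.n1}, n2={res.n2})")
for name, values in (("control", control), ("disease", disease)):
    box = box_summary(values)
    print(f"{name}: median {box.median:.3f} "
          f"(IQR {box.p25:.3f}-{box.p75:.3f}, n={box.n})")
print()
print("With n1 + n2 = 14 tie-free values the p-value is exact, computed by")
print("enumerating all 3432 rank assignments; whiskers (10th/90th) would")
print("only be reported for n >= 10 per group.")
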