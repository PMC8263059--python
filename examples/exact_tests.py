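"""Exact small-sample statistics, as used for n = 6-12 cell comparisons.

Run from the repository root::

    python examples/exact_tests.py
"""

import numpy as np

import b63osc as b

# paired comparison: oscillation period before vs after a manipulation
before = np.array([52.0, 61.0, 58.0, 49.0, 66.0, 57.0])
after = np.array([71.0, 80.0, 69.0, 62.0, 90.0, 75.0])
res = b.paired_signed_rank(before, after)
print(f"paired signed rank: {res.statistic_name} = {res.statistic:g}, "
      f"p = {res.p_value:.4g}, n = {res.n}")

# one-sample test of latencies against zero
latencies = np.array([1.2, 0.8, 2.5, 3.1, 0.4, 1.9, 2.2, 1.1])
res = b.one_sample_signed_rank(latencies)
print(f"one-sample signed rank: {res.statistic_name} = {res.statistic:g}, "
      f"p = {res.p_value:.4g}, n = {res.n}")

# two independent groups (e.g. treated vs control cells)
control = np.array([55.0, 58.0, 61.0, 52.0, 60.0, 57.0])
treated = np.array([78.0, 85.0, 92.0, 74.0, 88.0, 59.0])
res = b.rank_sum_exact(control, treated)
print(f"rank sum: {res.statistic_name} = {res.statistic:g}, "
      f"p = {res.p_value:.4g}, n1 = {res.n}, n2 = {res.n2}")

# confidence interval helper
mean, half = b.mean_ci95([58.0, 61.0, 55.0, 63.0, 57.0, 49.0])
print(f"mean period {mean:.1f} +/- {half:.1f} s (95% CI)")
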