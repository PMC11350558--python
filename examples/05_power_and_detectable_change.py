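"""Sample size and minimum detectable change for study planning.

The minimum detectable change for a subset is d x SD of its repeated
measurements (d = 0.5, a medium effect); the companion sample-size
computation inverts the exact noncentral-t power function for a
two-sided two-sample comparison.
"""

import numpy as np

from immunogate.variance import detectable_change, required_n, two_sample_power

n_exact, n_normal = required_n(cohens_d=0.5, power=0.80, alpha=0.05)
print(f"d=0.5, power 80%, alpha 0.05 (two-sided): "
      f"{n_exact} animals per group (exact noncentral t), "
      f"{n_normal} by the normal approximation")
for d in (0.2, 0.5, 0.8, 1.2):
    n, _ = required_n(d)
    print(f"  d={d:>4}: n={n:4d} per group  (power at that n: {two_sample_power(n, d):.3f})")

rng = np.random.default_rng(0)
leukocytes = rng.normal(3100, 730, 25)  # simulated repeated leukocyte counts, cells/µL
m = detectable_change(leukocytes, cohens_d=0.5)
print(f"\nleukocyte series: mean {leukocytes.mean():.0f} cells/µL, SD {leukocytes.std(ddof=1):.0f}")
print(f"minimum detectable change: {m.mdc_cells:.1f} cells/µL ({m.mdc_relative_pct:.1f}% of the mean)")
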