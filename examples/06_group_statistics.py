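"""Two-branch group comparison, the way day groups are compared.

Normality is tested per sample (Shapiro–Wilk); normal pairs use Welch's t
test with mean ± SD descriptives, non-normal pairs fall back to
Mann–Whitney U with median (IQR).
"""

import numpy as np

from infarct3d import compare_groups

rng = np.random.default_rng(3)

# lesion counts per lobe: normal-ish → t branch
day1_counts = rng.normal(10, 2, size=6)
day7_counts = rng.normal(40, 6, size=6)
c = compare_groups(day1_counts, day7_counts, variable="n_infarcts",
                   labels=("day 1", "day 7"))
print(f"{c.variable}: {c.describe(0)} vs {c.describe(1)} — "
      f"{c.test_used} test, p = {c.p_value:.2e}, "
      f"{'significant' if c.significant else 'not significant'}")

# single-lesion volumes: heavy-tailed → Mann–Whitney branch
vol_a = rng.lognormal(mean=8.0, sigma=1.2, size=30)
vol_b = rng.lognormal(mean=8.6, sigma=1.2, size=30)
c = compare_groups(vol_a, vol_b, variable="single_lesion_volume",
                   labels=("day 1", "day 7"))
print(f"{c.variable}: {c.describe(0)} vs {c.describe(1)} — "
      f"{c.test_used} test, p = {c.p_value:.3f} "
      f"(normality p = {c.normality_p[0]:.3f}, {c.normality_p[1]:.3f})")
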