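"""Simulate a two-class cohort of phenotyped cell point patterns.

Class 1 plants an Epithelial->CTL spatial coupling (80% of CTLs cluster
within ~20 um of an epithelial cell); class 2 has independent patterns.
The cross-coupling statistic (neighbor count normalized by the
independence expectation) is ~1 for independent patterns and rises with
planted coupling.
"""

import numpy as np

from phenodict import default_cohort_spec, empirical_cross_coupling, simulate_cohort

spec = default_cohort_spec(n_subjects_per_class=5, seed=1)
tables = simulate_cohort(spec)
print(f"{len(tables)} images, window {spec.window.width_um:.0f} x "
      f"{spec.window.height_um:.0f} um, phenotypes: {', '.join(spec.phenotypes)}")

first = tables[0]
print(f"\nimage {first.image_id} (class {first.class_label}): {len(first)} cells")
for p in first.phenotypes:
    print(f"  {p:<11} {len(first.positions(p)):>5}")

for cls in (1, 2):
    stats = [
        empirical_cross_coupling(t, ("Epithelial", "CTL"), radius_um=40.0)
        for t in tables
        if t.class_label == cls
    ]
    print(f"\nclass {cls} Epithelial->CTL coupling statistic: "
          f"{np.mean(stats):.3f} (1.0 = independent)")
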