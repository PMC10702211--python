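"""Simulate a small ground-truth gaze cohort and look at what it contains.

Children are drawn from two archetype gaze patterns — holistic (broad
ROIs over face center and contour) and analytic (tight ROIs on the eyes
and face center) — and expanded to raw 90 Hz binocular samples with
blinks and tracker noise.
"""

import numpy as np

from gazehmm import CohortSpec, simulate_cohort

spec = CohortSpec(n_children=6, holistic_fraction=0.5, rng_seed=1)
gaze, truth, scores = simulate_cohort(spec)

print("gaze samples:", len(gaze), "rows "
      f"({spec.n_children} children x {len(spec.faces)} faces x 720 samples)")
print("\nper-child ground truth (archetype, true H-A, fixation counts):")
print(truth.to_string(index=False))
print("\nsynthetic cognitive scores (negatively related to true H-A):")
print(scores.to_string(index=False))
print("\nfraction of samples lost to blinks:",
      round(float((gaze["l_valid"] == 0).mean()), 4))
# A positive true_ha means the child's fixations are better explained by
# the holistic archetype than the analytic one; scores fall as H-A rises.
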