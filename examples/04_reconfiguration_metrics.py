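"""Per-subject reconfiguration metrics from labeled eigenvector series.

Three metric families: frequency (occurrence, dwell time, switch count,
transition probabilities), transition distance (L1 step sizes between
consecutive LE(t), per state switch), and idiosyncrasy (L1 distance to
the cohort state medians).
"""

import numpy as np

from dfcstates import (
    metric_vector,
    run_average,
    run_profile,
)

rng = np.random.default_rng(4)

# a toy labeled series: 2 states in 6 dimensions
medians = np.array([[-0.5] * 6, [-0.4] * 3 + [0.4] * 3])
labels = np.array([1, 1, 1, 2, 2, 2, 2, 1, 1, 2, 2, 1])
le = medians[labels - 1] + rng.normal(0, 0.05, size=(12, 6))

profiles = [run_profile(le, labels, medians)]
avg = run_average(profiles)
vec, names = metric_vector(avg)

print(f"k=2 metric vector has {len(vec)} entries "
      f"(2k+1+k^2 frequency, k^2 distance, k idiosyncrasy)")
print(f"occurrence: {np.round(avg.occurrence, 3)}  (fraction of timepoints)")
print(f"dwell:      {np.round(avg.dwell, 2)}  (mean visit length, timepoints)")
print(f"switches:   {avg.transition_number:.0f}")
print("transition probabilities (rows: from-state, incl. self):")
print(np.round(avg.transition_prob, 3))
print("transition distances (mean L1 step per switch type):")
print(np.round(avg.transition_dist, 3))
print(f"idiosyncrasy (mean L1 to state median): {np.round(avg.idiosyncrasy, 3)}")
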