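"""Rod-visibility probability: closed form, Monte-Carlo oracle, correction.

A CETP-like rod (length 8.5 nm) standing radially on a spherical particle
is hidden in projection whenever its tip stays inside the particle
silhouette.  This script evaluates the closed-form visibility probability
P(D, l) at two diameters, cross-checks it against the orientation-sampling
Monte-Carlo estimate, and shows how an observed per-particle mean count is
corrected by dividing by P.
"""

import numpy as np

from lipocurv.occlusion import (
    BinnedSeries,
    VisibilityModel,
    correct_binned_counts,
    visibility_probability,
    visibility_probability_mc,
)

L = 8.5  # protrusion length, nm

for D in (15.0, 40.0):
    p = visibility_probability(D, L)
    p_mc, se = visibility_probability_mc(D, L, n=1_000_000, seed=1)
    print(f"D = {D:5.1f} nm:  P closed form = {p:.4f},  Monte Carlo = {p_mc:.4f} ± {se:.4f}")

# an observed mean of 2.0 bound rods per particle at D = 15 nm understates
# the true mean because ~12% of rods point toward/away from the viewer:
series = BinnedSeries(
    bin_centers=np.array([15.0]), values=np.array([2.0]),
    bin_step=2.17, n_per_bin=np.array([500]),
)
corrected = correct_binned_counts(series, VisibilityModel(l=L))
print(f"\nobserved mean count 2.00 at D = 15 nm  ->  corrected {corrected.values[0]:.3f}")
print("(the correction divides by P, undoing the orientation-averaged masking)")
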