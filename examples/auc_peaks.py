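"""Sedimentation-distribution peak fitting across cation states.

The sensor compacts as divalent cations bind: the sedimentation
coefficient s grows from the apo state (4.18 S) through the ~2Mg2+ state
(4.33 S) to the Ca2+-saturated state (4.45 S).  Each state's
s-distribution is fit with a 3-parameter Gaussian.
"""

import numpy as np

from tncfret import GaussianPeak, fit_gaussian_peak, simulate_auc_distribution

STATES = {"apo (EDTA)": 4.18, "~2 Mg2+ (EGTA/Mg)": 4.33, "3 Ca2+ (saturated)": 4.45}

grid = np.arange(3.0, 5.5 + 0.005, 0.01)
print("state                true s    fitted s   delta")
for i, (label, s_true) in enumerate(STATES.items()):
    s, freq = simulate_auc_distribution(
        [GaussianPeak(1.0, s_true, 0.12)], grid, noise_sd=0.01, seed=20 + i
    )
    fit = fit_gaussian_peak(s, freq)
    print(f"{label:<20} {s_true:5.2f} S   {fit.s_mean:6.3f} S   {fit.delta:.3f}")
print("\nLarger s at fixed mass means a more compact shape: the fitted means")
print("reproduce the progressive compaction as cations load the EF hands.")
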