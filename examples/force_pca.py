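"""Skinned-fiber force-pCa analysis: QC thresholds and Hill fitting.

A fiber preparation passes QC when TnC extraction leaves < 20% residual
force and reconstitution recovers > 60% of the pre-extraction force.
Normalized force-pCa data are then fit to the Hill relation with the
numerator fixed at 100%.
"""

import numpy as np

from tncfret import SimulationConfig, fit_hill_force, force_recovery, simulate_titration

qc = force_recovery(force_pre=100.0, force_post_extraction=15.0,
                    force_post_reconstitution=70.0)
print(f"extraction residual: {qc.extraction_residual_pct:.0f}% "
      f"(< 20% required) -> ok: {qc.extraction_ok}")
print(f"force recovery:      {qc.recovery_pct:.0f}% "
      f"(> 60% required) -> ok: {qc.recovery_ok}")

cfg = SimulationConfig(seed=6, noise_sd=2.0, mode="hill",
                       model_params=dict(model="force", p50=5.74, n=1.37))
series = simulate_titration(cfg, np.linspace(8.0, 4.0, 12), replicates=6,
                            response_kind="normalized_force")
fit = fit_hill_force(series)
print(f"\nforce-pCa Hill fit (12 pCa points x 6 fibers, 2% noise):")
print(f"  pCa50 = {fit.p50:.3f} +/- {fit.se['pca50']:.3f}")
print(f"  n_H   = {fit.n_h:.2f} +/- {fit.se['n_h']:.2f}")
print("  pCa50 is the Ca2+ sensitivity of force; n_H reports thin-filament")
print("  cooperativity. A ~0.2 unit rightward shift vs WT-TnC would indicate")
print("  mild desensitization by the attached fluorophores.")
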