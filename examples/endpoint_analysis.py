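"""End-point FRET analysis: chelated -> saturating Ca2+ -> re-chelated.

Simulates the three-condition protocol for the wild-type CTV-TnC sensor
(9 excitation wavelengths, realistic noise), then runs the full analysis:
spectral unmixing, direct-excitation correction, per-condition F_R means,
and the end-point signal dF_R with its reversibility diagnostic.
"""

from tncfret import (
    DEFAULT_CA_CONTRIBUTIONS,
    KNOCKOUT_PANEL,
    SimulationConfig,
    analyze_endpoint,
    simulate_endpoint_experiment,
)

config = SimulationConfig(seed=1, noise_sd=0.2)  # ~0.2% of donor amplitude
dataset = simulate_endpoint_experiment(
    KNOCKOUT_PANEL["CTV-TnC WT"], DEFAULT_CA_CONTRIBUTIONS, "Ca-in-EDTA", config
)
result = analyze_endpoint(dataset)

print("condition           mean F_R    SE")
for cond in result.condition_order:
    print(f"{cond:<18}  {result.mean_fr[cond]:8.4f}  {result.se_fr[cond]:.4f}")
print(f"\ndelta F_R = {result.delta_fr:.4f} +/- {result.delta_fr_se:.4f}"
      f"   (generator truth {dataset.true_delta_fr:.3f})")
print(f"reversibility gap |F_R(initial) - F_R(final)| = "
      f"{result.reversibility_gap:.4f}  -> reversible: {result.reversible}")
print("\nThe Ca-saturated condition raises F_R by the summed contributions of")
print("the three EF hands; the re-chelated condition returns to the initial")
print("level, confirming the signal change is reversible cation binding.")
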