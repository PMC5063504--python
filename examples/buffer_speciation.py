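"""Metal-chelator speciation: designing titration and fiber solutions.

Computes (i) how much total Mg must be added to a 2 mM EGTA + 5 mM NTA
titration buffer to hold 2 mM free Mg2+, and (ii) the free-ion state of a
simple fiber-style solution.  Constants are apparent 1:1 association
constants at pH 7.0 (shipped representative values; replace with your own
calibrated table for quantitative work).
"""

from tncfret import BufferSystem, pX, solve_free, total_for_free

# -- inverse problem: total Mg for 2 mM free in the titration buffer
buffer = BufferSystem(metals={"Mg": 0.0}, ligands={"EGTA": 2e-3, "NTA": 5e-3})
total = total_for_free(buffer, "Mg", target_free=2e-3)
print(f"titration buffer (2 mM EGTA + 5 mM NTA, pH {buffer.pH}):")
print(f"  total Mg needed for 2 mM free Mg2+: {total * 1e3:.2f} mM")

state = solve_free(buffer.with_total("Mg", total))
for lig in buffer.ligands:
    print(f"  Mg bound to {lig}: {state.complexes[('Mg', lig)] * 1e3:.3f} mM")
print(f"  mass-balance residual: {state.max_mass_balance_residual:.1e} (relative)")

# -- forward problem: free Ca2+ in an EGTA-buffered activating solution
fiber = BufferSystem(
    metals={"Ca": 6.8e-3, "Mg": 1.2e-3},
    ligands={"EGTA": 7e-3, "ATP": 2.5e-3},
)
state = solve_free(fiber)
print("\nfiber-style solution (7 mM EGTA, 2.5 mM ATP):")
print(f"  free Ca2+ = {state.free['Ca']:.3e} M  ->  pCa {pX(state.free['Ca']):.2f}")
print(f"  free Mg2+ = {state.free['Mg']:.3e} M  ->  pMg {pX(state.free['Mg']):.2f}")
print("  pCa/pMg are the titration axes used throughout the fitting modules.")
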