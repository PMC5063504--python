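# tncfret

Analysis pipeline for **TnC-based FRET sensors** of divalent cations:
cardiac troponin C (cTnC) flanked by a donor (Cerulean-like CFP) and an
acceptor (Venus-like YFP) fluorescent protein reports Ca²⁺ and Mg²⁺
binding through changes in Förster resonance energy transfer.  The
package converts raw fluorometer emission scans into the FRET-ratio
statistic, binding affinities, and per-EF-hand structural contributions,
and ships a seeded synthetic fluorometer so the whole pipeline runs and
tests without instrument data.

It is written for quantitative protein biophysicists working with
genetically encoded indicators, equilibrium titrations, skinned-fiber
mechanics, or sedimentation-velocity data.

## The models

**Spectral unmixing and the FRET ratio.**  Each emission scan
(445–610 nm) is a linear mix of known donor and acceptor reference
shapes; least squares gives the amplitudes *F*<sub>Don</sub> and
*F*<sub>Acc</sub>.  The acceptor channel splits into a FRET-driven and a
direct-excitation part,

  *F*<sub>Acc</sub> = *F*<sub>AccFRET</sub> + *F*<sub>AccDirect</sub>,

where *F*<sub>AccDirect</sub> is estimated from an acceptor-only control
normalized at the acceptor's direct-excitation maximum (515 nm).  The
FRET ratio

  *F*<sub>R</sub> = *F*<sub>AccFRET</sub> / *F*<sub>Don</sub>

is amplitude-invariant and therefore independent of excitation
wavelength.  An end-point experiment (chelated → 400 µM Ca²⁺ →
re-chelated) is summarized by
ΔF<sub>R</sub> = F<sub>R</sub>(Ca²⁺) − ½[F<sub>R</sub>(initial) + F<sub>R</sub>(final)],
averaged over a 9-wavelength excitation ladder (433 → 400 nm).

**Titration fitting.**  Full-range responses are fit in pX = −log₁₀[ion]:
a force–pCa Hill relation *F* = 100 / (1 + 10^(n<sub>H</sub>(pCa − pCa₅₀)));
a single Hill *f* = F<sub>min</sub> + F<sub>max</sub> / (1 + 10^(n(pX − pX₅₀)))
for Mg²⁺; and a biphasic double Hill (two components, the second amplitude
typically negative) for Ca²⁺.  Midpoints convert to association constants
as K<sub>a</sub> = 10^(pX₅₀) (reported at 2 significant figures).
Sedimentation-coefficient peaks are fit with a 3-parameter Gaussian.

**Buffer speciation.**  Free/bound metal concentrations in multi-chelator
buffers (EGTA, NTA, EDTA, ATP; apparent 1:1 constants at fixed pH) are
solved from the coupled mass-balance equations, forward (totals → free)
and inverse (target free → required total).

**EF-hand decomposition.**  Signals from a knockout-construct panel
(sites II/III/IV inactivated singly and in combination) are solved as a
linear system under the independence assumption, yielding per-site
contributions, a baseline, and a check of additivity against the
wild-type signal.

## Worked example

`examples/` holds one narrative script per capability.
`python examples/endpoint_analysis.py` simulates a noisy three-condition
end-point experiment for the wild-type sensor and analyzes it:

```
condition           mean F_R    SE
chelated              0.2498  0.0002
Ca-saturated          0.4541  0.0002
re-chelated           0.2499  0.0002

delta F_R = 0.2042 +/- 0.0002   (generator truth 0.204)
reversibility gap |F_R(initial) - F_R(final)| = 0.0001  -> reversible: True
```

The Ca-saturated condition raises F<sub>R</sub> by the summed per-site
contributions (−0.120 + 0.224 + 0.100 = 0.204) and the signal reverses on
re-chelation.  `examples/titration_fitting.py` fits a simulated biphasic
Ca²⁺ titration and prints the recovered affinities
(pCa₅₀₁ ≈ 7.2, K<sub>a</sub> ≈ 1.6×10⁷ M⁻¹ for the C-domain sites;
pCa₅₀₂ ≈ 5.5 with a negative amplitude for the N-domain site), and
`examples/efhand_decomposition.py` runs the full
simulate → unmix → end-point → decompose chain on the five-construct
panel.

A thin CLI wraps the same functions
(`tncfret simulate|unmix|endpoint|speciate|fit|decompose|run`), e.g.
`tncfret run --seed 3 --out out/` executes the panel pipeline end to end.

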