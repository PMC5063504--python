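# Methods

## Scope and model assumptions

The pipeline analyzes emission spectra of a two-fluorophore FRET sensor
built on cardiac troponin C under the sole photophysical assumption of
**linear mixing**: every scan is a nonnegative combination of a donor and
an acceptor reference emission shape, plus additive detector noise.  No
lifetime, anisotropy, photobleaching, inner-filter or scatter effects are
modeled, and no three-component unmixing is attempted.  The FRET ratio
F_R = F_AccFRET / F_Don is treated as the primary signal because it
cancels all multiplicative factors (excitation intensity, PMT gain, donor
excitation efficiency), which is what makes it excitation-wavelength
invariant.

Binding is modeled at equilibrium only.  The EF-hand decomposition
assumes the three sites contribute independently and additively to F_R;
the package does not model inter-site cooperativity, and deviations from
additivity are surfaced (not corrected) by the WT-comparison check.

## Synthetic fluorometer

The generator (`tncfret.simulate`) emulates the end-point and titration
protocols of a cuvette spectrofluorometer:

- **Scan window** 445–610 nm at 1 nm; **excitation ladder**
  {433, 424, 420, 418, 414, 410, 408, 404, 400} nm; acceptor
  direct-excitation maximum 515 nm.  The acceptor *emission* peak
  (525 nm) and the 515 nm peak-read/normalization wavelength are distinct
  configuration values, deliberately not conflated.
- **Reference shapes** are width-growing Gaussians (SD increases linearly
  past the peak), i.e. smooth right-skewed peaks with a long red tail —
  the qualitative shape of fluorescent-protein emission.  Donor: peak
  475 nm, SD 14 nm, skew 0.35; acceptor: peak 525 nm, SD 12 nm, skew
  0.30.  Because the analysis only assumes linear mixing of known shapes,
  the exact parametric family is immaterial; the defaults give a Gram
  matrix condition number ≈ 2, i.e. a very well-posed unmixing problem.
- **Direct excitation** of the acceptor follows a log-normal profile in
  excitation wavelength, 1.0 at 515 nm, log-width 0.08, giving
  profile(433)/profile(515) ≈ 0.10 — direct excitation is a minor
  correction at donor wavelengths and smaller still toward 400 nm.  The
  profile is configuration, never hard-coded into the analysis.
- **Donor brightness vs λ_ex** is a single scalar (1.0 at 433 nm → 0.55
  at 400 nm).  It scales both F_Don and F_AccFRET, so F_R is unaffected;
  the generator documents this invariance rather than depending on it.
- **Noise** is additive i.i.d. Gaussian per wavelength point (PMT at
  fixed voltage).  Default amplitudes: donor 100 a.u., direct-excitation
  amplitude 10 a.u. at 515 nm, noise SD 0–0.5 a.u. depending on the
  experiment.  A Poisson (shot-noise) mode is a possible extension, not
  implemented.
- **End-point semantics.**  True condition-level F_R = resting level
  (default 0.25, the apo sensor) + Σ contributions of occupied active
  sites; conditions 1 and 3 share the same truth, so reversibility holds
  by construction and the end-point signal ΔF_R equals the sum of the
  active sites' contributions exactly.  The shipped per-site defaults are
  the sensor family's characterization values (Ca: II −0.120, III
  +0.224, IV +0.100, baseline 0.010; Mg: III +0.079, IV +0.114, baseline
  0.094), overridable in configuration.  The "baseline" (signal of the
  construct with no functional EF hand) enters simulated *panel signals*
  as a common offset and is re-estimated by the decomposition; it is not
  part of a single construct's cation response.

What passing tests on synthetic data do **not** show: robustness to
baseline drift, scatter, bleaching, pipetting/dilution errors, spectral
shifts of the fluorophores with environment, or non-Gaussian detector
noise.  Real-data use should validate the reference shapes and the
direct-excitation profile against measured controls.

## Numerical choices

- **Unmixing** is unconstrained linear least squares (`numpy.lstsq`).
  Amplitudes may go slightly negative under noise and are reported
  unclipped with a `negative_amplitude` flag — clipping at zero would
  bias near-zero components.  A loud warning is emitted only when an
  amplitude is negative beyond 3× the scan's residual noise.  The design
  matrix is refused above condition number 1e8; reference shapes are
  linearly interpolated onto the scan grid and extrapolation is refused.
- **Direct-excitation normalization** uses a dedicated 515 nm scan of the
  sample per condition (the generator provides it); the control ratio
  r(λ_ex) is computed by unmixing both control scans — unmixing rather
  than peak reads, for consistency with the rest of the pipeline.
- **End-point summary**: mean ± SE of F_R across excitation wavelengths
  (SE = sample SD / √n); ΔF_R averages the per-wavelength contrasts.  The
  dataset is flagged non-reversible when |F_R(initial) − F_R(final)|
  exceeds 3× its propagated SE.
- **Hill fits** (lmfit least squares): offsets/amplitudes initialized
  from response extrema, Hill coefficients started at 1 and bounded to
  [0.2, 6], midpoints multi-started on the {0.25, 0.5, 0.75} quantiles of
  the observed pX range (all ordered pairs for the double Hill); best
  residual wins.  Double-Hill components are relabeled after convergence
  so component 1 has the larger pX₅₀ (higher affinity), ties broken by
  amplitude magnitude.  Midpoints closer than 0.3 pX units raise a
  `weakly_separated` flag; an amplitude within 2 SE of zero raises a
  `component_weak` flag rather than asserting a meaningless midpoint.
  The force–pCa numerator is fixed at 100 (data are normalized to
  saturating force); the sanity bound [−5, 110] % is widened by 3× the
  replicate-estimated noise so legitimate scatter around 0/100% is not
  rejected.  Non-normalized F_R data are fit directly, with no
  pre-scaling.
- **Flat-data guard** (single Hill): the fit refuses when the span of
  replicate-averaged responses is below 5× the pooled replicate SD
  scaled by √replicates ("no transition").
- **Speciation solver**: ligand unknowns are eliminated in closed form
  given the free metals, leaving a small metals-only system solved by a
  damped fixed point (deterministic start at free = total) plus a Newton
  polish on log concentrations; stiff near-equivalence systems fall back
  to Gauss–Seidel sweeps of bracketed 1-D solves.  Every solve asserts
  mass balance to 1e-10 relative or raises.  The inverse problem uses
  Brent's method on the strictly increasing total → free map, bracketed
  by [target, target + total ligand capacity]; round trips hold to 1e-9
  relative.  Constants are apparent, pH-conditional, 1:1 only; the
  shipped table is labeled representative and user-overridable, and no
  quantitative claim sharper than ~25% should rest on it.
- **Decomposition** is weighted least squares (weights 1/SE² when SEs are
  supplied) on a design of active-site indicators plus a baseline column
  of ones; exactly determined panels give the exact solve.  Rank
  deficiency raises an error naming the confounded columns.  Parameter
  SEs propagate via (XᵀWX)⁻¹.
- **Peak reads** take the nearest grid point, ties to the lower
  wavelength.  **K_a reporting** rounds to 2 significant figures.
- Serialization uses full-precision float repr everywhere, so
  write → read round trips are bit-exact.

## Problem sizes

Stochastic parameter-recovery runs (tests and `scripts/acceptance.py`)
use the study's protocol sizes: double-Hill Ca²⁺ titrations with 25 pCa
points 9.5→4.0 × 4 replicates at noise SD 0.005; single-Hill Mg²⁺ with 15
pMg points 5.5→1.5 × 4 replicates; force–pCa with 12 points 8→4 × 6
replicates at 2% noise; each averaged over 20 seeded runs.
Sedimentation fits use s ∈ [3.0, 5.5] at 0.01 S.

## Known limitations

- Apparent constants only: no proton balance, ionic-strength or
  temperature corrections; 1:1 stoichiometry (adequate for
  EGTA/EDTA/NTA/ATP with Ca²⁺/Mg²⁺); no enzymatic ATP regeneration.
- No kinetics (on/off rates), no Bayesian or global multi-dataset
  fitting, no statistical comparison tests between fits.
- The double-Hill model is weakly identified when one amplitude is small
  or the midpoints nearly coincide; the fitter flags these cases instead
  of suppressing them, and flagged midpoints should not be interpreted.
- The decomposition's independence assumption is tested only through the
  WT-additivity check; a violation is reported, not modeled.
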