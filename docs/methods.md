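# Methods

This note documents the models behind `phasemammo`, the defaults and
why they were chosen, what the synthetic phantoms do and do not
emulate, and the numerical conventions that matter for reproducing its
outputs.

## Source model

X-rays are produced by inverse Compton scattering of laser photons off
relativistic electrons; for head-on collision and backscattering

    E_x = 4 γ² E_L,    γ = E_e / E_0,

with `E_0 = 0.511 MeV`.  The model is exactly invertible
(`electron_energy_for`), and the off-axis energy falloff of the Compton
cone is *not* modelled: the beam is treated as monochromatic across the
collimated cone.  Defaults place the operating point at 25 keV with a
1.2 eV (≈1 μm infrared) laser photon energy, a 4 mrad full cone and a
16 m sample distance, giving a 64 mm footprint.  The total flux default
of 2.4·10¹⁰ photons/s divided by the footprint area yields a
sample-plane fluence rate of ~7.5·10⁶ mm⁻²s⁻¹.  The spectrum container
stores *sample-plane fluence rate* per energy bin because dosimetry
consumes fluence at the sample, not source flux.  Finite bandwidth is
modelled as a Gaussian line (`relative_bandwidth` = FWHM/peak,
truncated at ±3σ, bin sum exactly normalised); a single bin reproduces
the strictly monochromatic limit used everywhere by default.

## Phantoms

Phantoms are 2-D maps of projected line integrals at a 25 keV reference
energy: attenuation `a = ∫μ dz` (transmission `e^{−a}`), wavefront
phase `Φ = (2π/λ)∫δ dz`, and a small-angle-scatter strength `s` acting
multiplicatively on fringe visibility (`DF = e^{−s}`).  Maps are
decomposed per material class so `project()` can rescale attenuation by
`μ(E)/μ(E_ref)` from a shipped table; phase scales as `λ/λ_ref` and
scatter as `(E_ref/E)²`.  The material attenuation curves and the DgN
surface are **synthetic** fixtures with physical shape
(`μ(E) = A·E⁻³ + B`; see `scripts/make_tables.py`), not published
tables; the air `(μ_en/ρ)` values are the standard NIST data.

### Accreditation phantom

`gammex_like_phantom` builds a 4.5 cm breast-equivalent slab
(μ = 0.50 cm⁻¹ at 25 keV, 50% glandularity) containing 6 fibers,
5 microcalcification groups of 6 specks, and 5 masses on a grid of
64 px cells at 71 μm pitch, each with an object ROI fully inside the
insert and a paired object-free background ROI; a bottom slab strip is
the large background ROI for noise estimation.  Since vendor insert
compositions are not public, the per-rank attenuation contrasts are
calibration constants: they were set once, analytically, via
`Δa = −ln(1 − CNR_target/√N_bg)` with `N_bg` the expected background
counts of the default chain at 2.0 mGy, so that a clinical-dose
absorption image shows the canonical pattern — speck groups strongest
(CNR ≈ 44 at rank 1), masses intermediate, fibers weakest, and the
smallest mass near the CNR ≈ 1 detectability limit.  Scatter strengths
make the speck groups and masses dark-field-dominant, fibers weak
scatterers; the two largest masses carry an internal scatter ring that
only the dark-field channel reveals.  The construction is
deterministic; the `seed` argument is accepted for interface symmetry.

### Breast-texture phantom

`breast_texture_phantom` emulates anatomical clutter with a `1/f^β`
random field (β = 3 by default, relative amplitude 5% of the mean
projected attenuation) and can insert a spiculated lesion (disc plus
radial line bundle) and a microcalcification cluster with elevated
scatter.  It stands in for real mastectomy specimens only at the level
of image statistics: there is no anatomy, no thickness variation
toward the skin line, and no x-ray scatter background (only the
small-angle dark-field channel).  Tests passing on these phantoms
demonstrate correctness of the pipeline's estimators, not clinical
performance on real tissue.

## Interferometer and retrieval

The two-grating geometry defaults to `p₁ = 4.9 μm`, `p₂ = 5.0 μm`,
first fractional Talbot order at 25 keV.  A π/2 phase grating is
assumed because its design distance `p₁²/(2λ) = 24.2 cm` matches the
~25 cm inter-grating distance this geometry is operated at, while a π
grating would require ~6 cm; the choice is switchable in the config.
Phase stepping uses 8 uniform steps over one analyzer period (the
number of steps is not prescribed by the physics; 8 makes the DFT
estimator exact for a pure sinusoid and is conventional).  The
refraction coupling is geometric: a refraction angle
`α = (λ/2π)·∂Φ/∂x` (central differences over the pixel pitch, positive
toward increasing column index) shifts the stepping phase by
`(2πd/p₂)·α`.  Energy bins are simulated independently and expected
counts summed before Poisson sampling; the dark-field reduction is
multiplicative (`e^{−s}`), the standard small-angle-scattering
convention.  The reference fringe visibility defaults to 0.45, the
lower end of the 45-50% range such interferometers reach in practice.

Retrieval decomposes each pixel's stepping curve into mean `a₀` and
first DFT harmonic `(a₁, φ₁)`; for uniform full-period stepping this
coincides with the least-squares sinusoid fit (tested to 1e-9) and
inverts the noiseless forward model exactly (tested to 1e-10).
Degenerate pixels (`a₀ ≤ 0`, or `a₁/a₀` numerically zero so the phase
is undefined) are carried in an explicit validity mask, never as
sentinel values; masks propagate by union through the sample/reference
ratios.  Differential phase is wrapped to (−π, π]; phase unwrapping and
integration to a phase image are out of scope.

## Detector

The detector is an ideal photon counter at 71 μm pitch with an optional
Gaussian PSF applied to the expected counts before Poisson sampling
(signal is blurred, counting noise stays white).  The default
σ = 0.65 px (PSF FWHM ≈ 0.11 mm) is a realistic figure for a
Gd₂O₂S-scintillator flat panel; with it the simulated absorption system
resolves ~3.4-3.5 LP/mm at clinical noise levels, inside the 3-4 LP/mm
band such systems demonstrate on accreditation phantoms.  No detector
MTF beyond this blur, no scintillator afterglow, no gain maps.

## Dosimetry

Air kerma per bin is `K(E) = E·Φ(E)·t·(μ_en/ρ)_air(E)` with explicit
unit conversions (keV→J, mm⁻²→m⁻², Gy→mGy); mean glandular dose is

    MGD = Σ_E K(E) · 0.114 R/mGy · DgN(E, thickness, glandularity),

where 0.114 R/mGy (the reciprocal of 8.76 mGy/R) converts air kerma to
the legacy exposure unit DgN tables are normalised to; it appears
exactly once as a named constant.  DgN is interpolated linearly per
axis inside its grid and *never* extrapolated — out-of-grid queries
raise — because silent dose under-reporting is the failure mode that
matters.  The shipped DgN surface is synthetic (monotone increasing in
energy, decreasing in thickness and glandular fraction) and anchored at
DgN(25 keV, 4.5 cm, 0.5) = 1.15 mGy/R so that the default chain's MGD
rate is ~0.11 mGy/s: clinical 1-2 mGy doses then need 10-20 s
exposures, a realistic operating point.  Users who need physically
accurate dosimetry should replace `dgn_synthetic.csv` with literature
tables of the same CSV schema.

The thickness correction for MGD values reported at a wrong compressed
thickness maps the beam's aluminum half-value layer to an effective
monoenergy (via the shipped Al attenuation table, HVL = ln2/μ strictly
increasing with energy) and multiplies by
`DgN(E_eq, t_true)/DgN(E_eq, t_assumed)`.  This DgN-ratio construction
is one defensible reading of "corrected via the HVL and the two
thicknesses"; it is isolated in a single function and swappable.

Counter calibration is proportional (`counts = k·kerma`), so the
fluence-computed and counter-logged kerma routes agree exactly in
simulation; the ±10% band quoted for real ionization-chamber
cross-checks is a measurement statement, representable here only as a
configured perturbation.

## Image quality

**CNR** follows `(S̄₁ − S̄₂)/σ_BG` with sample standard deviation
(n−1) over a larger object-free background ROI.  The signed value is
kept in `CnrResult`; detectability scoring uses the magnitude, because
attenuating objects give negative contrast on count images while
detectability is sign-blind.  An object is "resolved" at |CNR| ≥ 1
(Rose-style threshold); the accreditation pass requires ≥4 fibers,
≥3 speck groups and ≥3 masses.  Human-observer scoring is explicitly
not modelled.

**Resolution** is the maximal spatial frequency at which the radially
averaged, Gaussian-smoothed image power spectrum crosses down through
twice the noise baseline.  Numerical choices: a Hann window before the
FFT (otherwise leakage from non-periodic image content lifts the
on-axis spectral tail and corrupts the baseline); smoothing σ = 0.5
frequency bins (radial averaging already supplies variance reduction;
heavier smoothing smears the band edge and biases the estimate high —
σ = 2 overshoots a known 3.0 cycles/mm cutoff by ~0.45 LP/mm);
baseline = median smoothed power in the top decile of frequencies below
Nyquist; last-crossing rule with linear interpolation between annuli.
The baseline is accepted as a *noise* floor only if the spectrum is
flat at the Nyquist radius, checked in the corner band 1.02-1.35×
Nyquist (reachable along the grid diagonals): white pixel noise keeps
its power there, a still-falling noiseless spectrum does not.  When no
valid crossing exists (pure noise, noiseless images) the estimator
raises rather than fabricating a number.  The quoted uncertainty is the
spread over the four image quadrants — one convention among several
possible (sub-regions, directions, repeats), chosen for being
computable from a single image.

**Dose-CNR law**: with Poisson noise, CNR ∝ √MGD; the suite checks the
log-log slope is 0.5 ± 0.05 across 0.5-4 mGy.

## Stitching and orchestration

Tiles overlap by a fixed width and blend with linear ramps: incoming
weight `(i+1)/(n+1)` at overlap position `i`, outgoing the complement,
so weights are strictly inside (0,1) (every acquired pixel contributes,
no zero-weight columns) and sum to one.  Blending is implemented in
lerp form `a + w·(b − a)`, which preserves constant fields bit for bit.
Stitching operates on *retrieved* channels, not raw stacks;
differential-phase tiles are blended as phasors `e^{iΔφ}` and the angle
re-taken, avoiding ramps across the ±π cut.  Tile offsets are exact by
construction (no sub-pixel registration), and flat-field correction of
real detector data is out of scope.

`run_dose_study` merges a user config over the packaged defaults,
plans each (modality, MGD) exposure through the dosimetry chain,
simulates tile by tile (2×2 grid, 16 px overlap by default), retrieves
and stitches, and scores CNR/resolution/accreditation.  One master seed
fans out via `numpy.random.SeedSequence` to per-stage and per-tile
children, all recorded in the report; identical configs and seeds
reproduce bit-identical CSVs.

## Problem sizes

The default accreditation phantom is 256×384 px (≈18×27 mm at 71 μm),
chosen so that every object class keeps a realistic pixel footprint
while a full five-modality dose study completes in seconds; the
forward/inverse and visibility checks run on 64-128 px tiles, and
stochastic checks (accreditation vote, dose-CNR slope) use 5-20 seeds.

## Known limitations

* No wave-optical propagation, partial-coherence fringe blur, grating
  imperfections or beam-profile vignetting; the interferometer is the
  idealised sinusoidal-fringe model.
* No x-ray scatter background (only the parametrised small-angle
  dark-field channel); no off-axis Compton energy falloff; source-size
  penumbral blur (<50 μm source at 16 m) is neglected.
* Dosimetric absolute accuracy is limited by the synthetic DgN surface;
  all dose-anchored results are self-consistent within the package's
  own chain.
* The differential-phase channel is scored only qualitatively (its
  differential nature makes mean-difference CNR meaningless); no phase
  integration is performed.
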