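# phasemammo

Simulation and image-quality analysis of grating-based phase-contrast
mammography at a compact inverse-Compton x-ray source.

## The problem

Absorption mammography struggles with the low soft-tissue contrast of
dense breasts, while phase-sensitive techniques (grating-based
differential-phase and dark-field imaging) have historically needed
doses far above radiological guidelines.  A quasi-monochromatic,
partially coherent beam from a compact inverse-Compton synchrotron
makes dose-compatible grating interferometry possible: the x-ray energy
can sit at the contrast/dose optimum and the beam coherence supports a
two-grating Talbot interferometer.

This package implements, as a tested and reusable pipeline, the
computational chain of such an experiment:

1. **Source model** — x-ray energy from the Compton relation
   `E_x = 4 γ² E_L` (γ = E_e/E_0), collimated-cone beam footprint, and
   a binned sample-plane fluence spectrum `Φ(E)`.
2. **Digital phantoms** — a mammography accreditation phantom
   (6 fibers, 5 microcalcification speck groups, 5 masses in a 4.5 cm
   breast-equivalent slab) and a 1/f^β textured breast phantom, stored
   as projected attenuation `∫μ dz`, wavefront phase `(2π/λ)∫δ dz` and
   small-angle-scatter maps with ground-truth ROI layouts.
3. **Talbot interferometer** — fractional Talbot design distance
   `d = m p₁²/(2λ)` (π/2 grating), phase-stepping stack synthesis with
   per-pixel expectation
   `N_s = (F/n) T [1 + V·e^{-∫σ dz}·cos(θ_s + φ₀ + (2πd/p₂)α)]`
   and Poisson counting noise.
4. **Retrieval** — per-pixel DFT decomposition of the stepping curve
   into mean, first-harmonic amplitude and phase; transmission
   `T = a₀ˢ/a₀ʳ`, differential phase `Δφ = wrap(φ₁ˢ − φ₁ʳ)` and dark
   field `DF = (a₁/a₀)ˢ/(a₁/a₀)ʳ`.
5. **Dosimetry** — air kerma per energy bin
   `K(E) = E·Φ(E)·(μ_en/ρ)_air(E)` and mean glandular dose
   `MGD = Σ_E K(E)·0.114 [R/mGy]·DgN(E, t, g)` with monoenergetic
   normalized glandular dose coefficients; exposure planning, aluminum
   half-value-layer thickness correction, counter calibration.
6. **Image quality** — CNR `(S̄₁ − S̄₂)/σ_BG`, power-spectrum
   resolution (maximal spatial frequency where the smoothed radial
   spectral power crosses twice the noise baseline), ACR-style
   accreditation scoring (≥4 fibers, ≥3 speck groups, ≥3 masses at
   |CNR| ≥ 1), linear-ramp tile stitching, and an end-to-end dose-study
   orchestrator.

## Worked example

```python
import phasemammo as pm

# 25 keV operating point: 1.2 eV laser photons on ~36.9 MeV electrons
source = pm.SourceConfig(pm.electron_energy_for(25.0, 1.2), 1.2)
spectrum = pm.make_spectrum(
    25.0, 0.0, pm.sample_plane_fluence_rate(source, 2.4e10), 1)

t = pm.exposure_time_for_mgd(2.0, spectrum, thickness=4.5, glandularity=0.5)
print(f"exposure for 2.0 mGy MGD: {t:.1f} s")      # 18.8 s

report = pm.run_dose_study(seed=1)                 # full phantom study
print(report.acr["mAC-2mGy/absorption"].resolved)
```

prints

```
exposure for 2.0 mGy MGD: 18.8 s
{'fiber': 5, 'calcification_group': 5, 'mass': 5}
```

meaning the beam needs ~19 s to deliver a clinical 2.0 mGy mean
glandular dose, and the simulated absorption image at that dose
resolves 5 fibers, 5 microcalcification groups and 5 masses at
|CNR| ≥ 1 — beyond the 4/3/3 accreditation minimum.  The scripts under
`examples/` walk through each capability (source and dose planning,
simulate/retrieve, the dose study, resolution analysis, stitching) and
print the numbers they compute.

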