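"""Phase stepping forward and inverse on a textured breast phantom.

Simulates a Talbot-interferometer phase-stepping scan (sample plus
reference) of a breast-like phantom with an inserted spiculated lesion,
retrieves the three contrast channels, and verifies that the noiseless
loop is exact.
"""

import numpy as np

import phasemammo as pm

phantom = pm.breast_texture_phantom(
    (128, 128), seed=1,
    lesion_spec={"center": (64, 64), "radius_px": 10, "contrast": 0.08,
                 "n_spiculae": 8, "calc_specks": 4, "calc_contrast": 0.3})
interferometer = pm.InterferometerConfig()  # p1=4.9 um, p2=5.0 um, 8 steps
print(f"design Talbot distance : {pm.talbot_distance(interferometer):.3f} m")

source = pm.SourceConfig(pm.electron_energy_for(25.0, 1.2), 1.2)
spectrum = pm.make_spectrum(
    25.0, 0.0, pm.sample_plane_fluence_rate(source, 2.4e10), 1)

sample = pm.simulate_stepping_stack(phantom, interferometer, spectrum, 14.0,
                                    seed=1)
reference = pm.simulate_stepping_stack(phantom, interferometer, spectrum,
                                       14.0, seed=2, with_sample=False)
image = pm.multimodal_retrieve(sample, reference)
print(f"median transmission    : {np.nanmedian(image.transmission):.3f}")
print(f"median dark field      : {np.nanmedian(image.dark_field):.3f}")
print(f"reference visibility   : {pm.median_visibility(reference):.3f}")

# noiseless loop: retrieval inverts the forward model exactly
s0 = pm.simulate_stepping_stack(phantom, interferometer, spectrum, 14.0,
                                noise=False)
r0 = pm.simulate_stepping_stack(phantom, interferometer, spectrum, 14.0,
                                noise=False, with_sample=False)
exact = pm.multimodal_retrieve(s0, r0)
err = np.abs(exact.transmission - np.exp(-phantom.projected_attenuation)).max()
print(f"noiseless T error      : {err:.2e}  (forward/inverse are exact)")
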