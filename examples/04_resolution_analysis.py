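"""Power-spectrum resolution estimation.

Demonstrates the 2x-noise-baseline criterion on a constructed field
with a known 3.0 cycles/mm band limit, and on a simulated clinical-dose
phantom image.
"""

import numpy as np

import phasemammo as pm
from phasemammo import pipeline
from phasemammo.errors import UndeterminedResolutionError

PITCH = 0.071  # mm

# known ground truth: hard radial cutoff at 3.0 cycles/mm + 1% noise
rng = np.random.default_rng(0)
fr = np.fft.fftfreq(256, d=PITCH)[:, None]
fc = np.fft.fftfreq(256, d=PITCH)[None, :]
mask = np.hypot(fr, fc) <= 3.0
field = np.real(np.fft.ifft2(np.fft.fft2(rng.standard_normal((256, 256)))
                             * mask))
field = field / field.std() + 0.01 * rng.standard_normal((256, 256))
res = pm.power_spectrum_resolution(field, PITCH)
print(f"constructed 3.0 cy/mm field -> {res.resolution:.2f} "
      f"+- {res.uncertainty:.2f} LP/mm")

# pure noise has no resolvable structure: the estimator refuses a number
try:
    pm.power_spectrum_resolution(rng.standard_normal((128, 128)), PITCH)
except UndeterminedResolutionError as exc:
    print(f"pure white noise          -> undetermined ({exc})")

# simulated 2.0 mGy absorption image of the accreditation phantom
cfg = pipeline.default_config()
cfg["acquisition"]["modalities"] = [{"mode": "absorption", "mgd_mgy": 2.0}]
report = pm.run_dose_study(cfg, seed=1)
row = report.quality_table.query("row_type == 'resolution'").iloc[0]
print(f"2.0 mGy phantom image     -> {row.resolution_lp_mm:.2f} "
      f"+- {row.resolution_unc_lp_mm:.2f} LP/mm")
# The simulated system resolves ~3.5 LP/mm, inside the 3-4 LP/mm band
# typical of mammography systems at this pixel pitch.
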