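"""Physical constants and unit conversions used across the package.

Internal unit conventions:

* photon energies in keV (laser photon energies are accepted in eV at the
  API boundary and converted here),
* lengths in the unit natural to each quantity (grating periods in um,
  distances in m, pixel pitch in mm), converted explicitly at use sites,
* fluence in photons / mm^2, air kerma and glandular dose in mGy.
"""

ELECTRON_REST_ENERGY_MEV = 0.511
"""Electron rest energy m_e c^2 in MeV."""

HC_KEV_NM = 1.23984193
"""Planck constant times speed of light, keV * nm (lambda[nm] = HC / E[keV])."""

KEV_TO_J = 1.602176634e-16
"""One keV in joules."""

ROENTGEN_PER_MGY_AIR = 0.114
"""Exposure-per-air-kerma conversion, R/mGy.

Reciprocal of 8.76 mGy/R (air kerma per roentgen).  Used to couple air
kerma to normalized glandular dose coefficients DgN, which are tabulated
in mGy per roentgen of entrance exposure.
"""

MM2_TO_M2 = 1.0e-6
GY_TO_MGY = 1.0e3


def wavelength_nm(energy_kev: float) -> float:
    """X-ray wavelength in nm for a photon energy in keV."""
    if energy_kev <= 0:
        raise ValueError("photon energy must be positive")
    return HC_KEV_NM / energy_kev


def wavelength_m(energy_kev: float) -> float:
    """X-ray wavelength in metres for a photon energy in keV."""
    return wavelength_nm(energy_kev) * 1.0e-9
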