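"""Regenerate the coefficient CSV fixtures under src/phasemammo/data/.

Three tables are produced:

* ``mu_en_air.csv`` — mass energy-absorption coefficient of dry air,
  densified from the standard NIST anchor grid onto 1 keV spacing by
  log-log interpolation (the physical convention for attenuation-type
  coefficients).
* ``al_attenuation.csv`` — linear attenuation of aluminum (mu in 1/mm)
  from NIST (mu/rho) anchors and rho = 2.699 g/cm^3; used to invert a
  half-value layer into an effective monoenergy.
* ``dgn_synthetic.csv`` — a SYNTHETIC stand-in for monoenergetic
  normalized glandular dose coefficients DgN(E, thickness,
  glandularity).  The published tables are not redistributable here, so
  a smooth, physically shaped surface is generated instead: DgN rises
  with energy (deeper penetration deposits a larger glandular share),
  falls with compressed thickness and with glandular fraction.  The
  overall constant anchors DgN(25 keV, 4.5 cm, 0.5) = 1.15 mGy/R so the
  default source chain delivers 1-2 mGy in 10-20 s exposures, matching
  realistic clinical operating points.
* ``materials_mu.csv`` — SYNTHETIC linear attenuation curves (1/cm) for
  the phantom material classes, modelled as mu(E) = A E^-3 + B
  (photoelectric + Compton shape) through two plausible anchor points
  per material; monotone decreasing over the tabulated range.

Run from the repository root:  python scripts/make_tables.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

DATA = Path(__file__).resolve().parents[1] / "src" / "phasemammo" / "data"

# NIST dry-air mass energy-absorption coefficients, cm^2/g.
NIST_AIR_E_KEV = np.array([10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 60.0, 80.0])
NIST_AIR_MUEN = np.array([4.742, 1.334, 0.5389, 0.1537, 0.06833, 0.04098,
                          0.03041, 0.02407])

# NIST aluminum mass attenuation coefficients, cm^2/g; rho = 2.699 g/cm^3.
NIST_AL_E_KEV = np.array([10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 60.0, 80.0])
NIST_AL_MU_RHO = np.array([26.23, 7.955, 3.441, 1.128, 0.5685, 0.3681,
                           0.2778, 0.2018])
AL_DENSITY = 2.699  # g/cm^3


def loglog_interp(x, xp, fp):
    return np.exp(np.interp(np.log(x), np.log(xp), np.log(fp)))


def write_mu_en_air():
    e = np.arange(10.0, 50.0 + 0.5, 1.0)
    muen_cm2_g = loglog_interp(e, NIST_AIR_E_KEV, NIST_AIR_MUEN)
    df = pd.DataFrame({"energy_keV": e,
                       "mu_en_over_rho_m2_per_kg": muen_cm2_g * 0.1})
    df.to_csv(DATA / "mu_en_air.csv", index=False, float_format="%.6g")


def write_al_attenuation():
    e = np.arange(10.0, 50.0 + 0.5, 1.0)
    mu_rho = loglog_interp(e, NIST_AL_E_KEV, NIST_AL_MU_RHO)
    mu_per_mm = mu_rho * AL_DENSITY / 10.0
    df = pd.DataFrame({"energy_keV": e, "mu_per_mm": mu_per_mm})
    df.to_csv(DATA / "al_attenuation.csv", index=False, float_format="%.6g")


def dgn_model(e_kev, thickness_cm, glandularity):
    """Synthetic DgN surface in mGy/R (see module docstring)."""
    shape = 1.0 - np.exp(-(((np.asarray(e_kev, float) - 8.0) / 14.0) ** 1.6))
    anchor = 1.0 - np.exp(-((25.0 - 8.0) / 14.0) ** 1.6)
    return (1.15 * shape / anchor
            * (np.asarray(thickness_cm, float) / 4.5) ** -0.6
            * (1.15 - 0.30 * np.asarray(glandularity, float)))


def write_dgn():
    e = np.arange(10.0, 50.0 + 0.5, 2.5)
    t = np.arange(2.0, 8.0 + 0.5, 1.0)
    g = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
    rows = []
    for ei in e:
        for ti in t:
            for gi in g:
                rows.append((ei, ti, gi, float(dgn_model(ei, ti, gi))))
    df = pd.DataFrame(rows, columns=["energy_keV", "thickness_cm",
                                     "glandularity", "dgn_mgy_per_R"])
    df.to_csv(DATA / "dgn_synthetic.csv", index=False, float_format="%.6g")


# Synthetic phantom material curves: mu(E) = A E^-3 + B through two anchors.
MATERIAL_ANCHORS = {
    # material: (mu at 15 keV, mu at 25 keV) in 1/cm
    "breast_50_50": (1.60, 0.50),
    "adipose": (1.20, 0.44),
    "glandular": (1.95, 0.56),
    "fiber_nylon": (1.70, 0.55),
    "calcification": (25.0, 6.00),
    "mass_tumor": (2.05, 0.58),
}


def write_materials():
    e = np.arange(10.0, 50.0 + 0.5, 1.0)
    cols = {"energy_keV": e}
    for name, (mu15, mu25) in MATERIAL_ANCHORS.items():
        a = (mu15 - mu25) / (15.0**-3 - 25.0**-3)
        b = mu25 - a * 25.0**-3
        cols[name] = a * e**-3.0 + b
    pd.DataFrame(cols).to_csv(DATA / "materials_mu.csv", index=False,
                              float_format="%.6g")


if __name__ == "__main__":
    DATA.mkdir(parents=True, exist_ok=True)
    write_mu_en_air()
    write_al_attenuation()
    write_dgn()
    write_materials()
    print(f"wrote tables to {DATA}")
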