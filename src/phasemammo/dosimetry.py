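"""Mean-glandular-dose chain for a quasi-monochromatic beam.

The dose delivered to the breast is computed in two steps.  First the
entrance air kerma per energy bin,

    K(E) = E * Phi(E) * (mu_en / rho)_air(E),

with ``Phi`` the photon fluence at the sample plane and
``(mu_en/rho)_air`` the mass energy-absorption coefficient of air.
Second, the mean glandular dose via monoenergetic normalized glandular
dose coefficients,

    MGD = sum_E K(E) [mGy] * 0.114 [R/mGy] * DgN(E) [mGy/R],

where the 0.114 R/mGy factor converts air kerma to the legacy exposure
unit in which DgN tables are expressed, and DgN is selected for the
compressed breast thickness and glandular fraction.

Clinical (polychromatic) MGD values reported by a mammography unit can
be corrected for a wrongly assumed breast thickness through the beam's
aluminum half-value layer: the HVL is mapped to an effective
monoenergy and the correction factor is the DgN ratio at the true vs
assumed thickness.

All table lookups are hard-bounded: a query outside the tabulated grid
raises :class:`~phasemammo.errors.TableRangeError` rather than
extrapolating, because silent dose under-reporting is the failure mode
that matters.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .constants import GY_TO_MGY, KEV_TO_J, MM2_TO_M2, ROENTGEN_PER_MGY_AIR
from .errors import InvalidInputError, TableRangeError
from .source import Spectrum

__all__ = [
    "MuEnTable",
    "DgNTable",
    "AlAttenuationTable",
    "DoseReport",
    "CounterCalibration",
    "air_kerma",
    "mean_glandular_dose",
    "dose_report",
    "thickness_correction_factor",
    "exposure_time_for_mgd",
    "calibrate_counter",
    "load_mu_en_air",
    "load_dgn_table",
    "load_al_attenuation",
]


class MuEnTable:
    """Mass energy-absorption coefficient of air, (mu_en/rho) in m^2/kg."""

    def __init__(self, energies_kev: np.ndarray, values_m2_per_kg: np.ndarray):
        e = np.asarray(energies_kev, dtype=float)
        v = np.asarray(values_m2_per_kg, dtype=float)
        if e.ndim != 1 or e.size < 2 or np.any(np.diff(e) <= 0):
            raise InvalidInputError("energy grid must be strictly ascending")
        if np.any(v <= 0):
            raise InvalidInputError("mu_en/rho values must be positive")
        self.energies = e
        self.values = v

    def __call__(self, energy_kev) -> np.ndarray:
        e = np.asarray(energy_kev, dtype=float)
        if np.any(e < self.energies[0]) or np.any(e > self.energies[-1]):
            raise TableRangeError(
                f"energy outside (mu_en/rho)_air table "
                f"[{self.energies[0]}, {self.energies[-1]}] keV")
        return np.interp(e, self.energies, self.values)


class DgNTable:
    """Monoenergetic normalized glandular dose coefficients, mGy/R.

    Gridded over (energy keV, compressed thickness cm, glandular
    fraction) with linear interpolation per axis and hard range errors
    outside the grid.
    """

    def __init__(self, energies: np.ndarray, thicknesses: np.ndarray,
                 glandularities: np.ndarray, values: np.ndarray):
        e, t, g = (np.asarray(x, dtype=float)
                   for x in (energies, thicknesses, glandularities))
        v = np.asarray(values, dtype=float)
        if v.shape != (e.size, t.size, g.size):
            raise InvalidInputError("DgN value grid shape mismatch")
        if np.any(v <= 0):
            raise InvalidInputError("DgN values must be positive")
        for axis in (e, t, g):
            if axis.size < 2 or np.any(np.diff(axis) <= 0):
                raise InvalidInputError("DgN axes must be strictly ascending")
        self.energies, self.thicknesses, self.glandularities = e, t, g
        self.values = v
        self._interp = RegularGridInterpolator(
            (e, t, g), v, method="linear", bounds_error=True)

    def __call__(self, energy_kev, thickness_cm, glandularity) -> np.ndarray:
        e = np.asarray(energy_kev, dtype=float)
        scalar = e.ndim == 0
        e = np.atleast_1d(e)
        pts = np.stack([e, np.broadcast_to(thickness_cm, e.shape),
                        np.broadcast_to(glandularity, e.shape)], axis=-1)
        try:
            out = self._interp(pts)
        except ValueError as exc:
            raise TableRangeError(f"DgN query outside table grid: {exc}") from exc
        return float(out[0]) if scalar else out


class AlAttenuationTable:
    """Linear attenuation of aluminum, used to map HVL to an energy.

    Stores mu(E) in 1/mm; the half-value layer HVL(E) = ln 2 / mu(E) is
    strictly increasing with energy over the diagnostic range, so it can
    be inverted for an effective monoenergy.
    """

    def __init__(self, energies_kev: np.ndarray, mu_per_mm: np.ndarray):
        e = np.asarray(energies_kev, dtype=float)
        mu = np.asarray(mu_per_mm, dtype=float)
        if np.any(np.diff(e) <= 0) or np.any(mu <= 0):
            raise InvalidInputError("invalid aluminum attenuation table")
        self.energies = e
        self.mu = mu
        self.hvl_mm = math.log(2.0) / mu

    def effective_energy(self, hvl_mm: float) -> float:
        h = self.hvl_mm
        if not (h[0] <= hvl_mm <= h[-1]):
            raise TableRangeError(
                f"HVL {hvl_mm} mm outside table range [{h[0]:.3f}, {h[-1]:.3f}]")
        return float(np.interp(hvl_mm, h, self.energies))


@dataclass
class DoseReport:
    """Air kerma and mean glandular dose for one acquisition."""

    kerma_per_bin: np.ndarray  # mGy
    total_kerma: float         # mGy
    mgd: float                 # mGy
    exposure_time: float       # s
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.kerma_per_bin = np.asarray(self.kerma_per_bin, dtype=float)
        if np.any(self.kerma_per_bin < 0) or self.mgd < 0:
            raise InvalidInputError("doses must be non-negative")
        if not math.isclose(self.total_kerma, float(self.kerma_per_bin.sum()),
                            rel_tol=1e-9, abs_tol=1e-15):
            raise InvalidInputError("total_kerma must equal the bin sum")

    def to_json(self, path) -> None:
        payload = {
            "kerma_per_bin_mGy": self.kerma_per_bin.tolist(),
            "total_kerma_mGy": self.total_kerma,
            "mgd_mGy": self.mgd,
            "exposure_time_s": self.exposure_time,
            "settings": self.settings,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _load_csv(name: str) -> pd.DataFrame:
    with resources.files("phasemammo.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")


def load_mu_en_air() -> MuEnTable:
    """Shipped (mu_en/rho)_air table (m^2/kg vs keV)."""
    df = _load_csv("mu_en_air.csv")
    return MuEnTable(df["energy_keV"].to_numpy(),
                     df["mu_en_over_rho_m2_per_kg"].to_numpy())


def load_dgn_table() -> DgNTable:
    """Shipped synthetic DgN(E, thickness, glandularity) surface.

    A physically shaped stand-in (monotone increasing in energy,
    decreasing in thickness and glandularity), anchored so the default
    25 keV chain reproduces realistic clinical exposure times; see
    scripts/make_tables.py for the generating model.
    """
    df = _load_csv("dgn_synthetic.csv")
    e = np.unique(df["energy_keV"])
    t = np.unique(df["thickness_cm"])
    g = np.unique(df["glandularity"])
    v = (df.sort_values(["energy_keV", "thickness_cm", "glandularity"])
         ["dgn_mgy_per_R"].to_numpy().reshape(e.size, t.size, g.size))
    return DgNTable(e, t, g, v)


def load_al_attenuation() -> AlAttenuationTable:
    """Shipped aluminum linear-attenuation table (1/mm vs keV)."""
    df = _load_csv("al_attenuation.csv")
    return AlAttenuationTable(df["energy_keV"].to_numpy(),
                              df["mu_per_mm"].to_numpy())


def air_kerma(spectrum: Spectrum, exposure_time: float,
              mu_en: MuEnTable | None = None) -> tuple[np.ndarray, float]:
    """Air kerma per bin and total, in mGy.

    ``K = E * Phi * t * (mu_en/rho)_air`` per bin, with E converted
    keV -> J, fluence mm^-2 -> m^-2 and Gy -> mGy.
    """
    if exposure_time < 0:
        raise InvalidInputError("exposure_time must be non-negative")
    if mu_en is None:
        mu_en = load_mu_en_air()
    coeff = mu_en(spectrum.bin_centers)
    fluence_m2 = spectrum.fluence_rate * exposure_time / MM2_TO_M2
    kerma = (spectrum.bin_centers * KEV_TO_J) * fluence_m2 * coeff * GY_TO_MGY
    return kerma, float(kerma.sum())


def mean_glandular_dose(kerma_per_bin: np.ndarray, energies: np.ndarray,
                        thickness: float, glandularity: float,
                        dgn: DgNTable | None = None) -> float:
    """MGD = sum_E K(E) * 0.114 R/mGy * DgN(E, thickness, glandularity)."""
    if dgn is None:
        dgn = load_dgn_table()
    k = np.asarray(kerma_per_bin, dtype=float)
    e = np.asarray(energies, dtype=float)
    if k.shape != e.shape:
        raise InvalidInputError("kerma and energy arrays must match")
    coeffs = dgn(e, thickness, glandularity)
    return float(np.sum(k * ROENTGEN_PER_MGY_AIR * coeffs))


def dose_report(spectrum: Spectrum, exposure_time: float, thickness: float,
                glandularity: float, mu_en: MuEnTable | None = None,
                dgn: DgNTable | None = None) -> DoseReport:
    """Full kerma + MGD report for one exposure."""
    kerma, total = air_kerma(spectrum, exposure_time, mu_en)
    mgd = mean_glandular_dose(kerma, spectrum.bin_centers, thickness,
                              glandularity, dgn)
    return DoseReport(kerma, total, mgd, exposure_time, settings={
        "thickness_cm": thickness, "glandularity": glandularity,
        "mean_energy_keV": spectrum.mean_energy,
    })


def thickness_correction_factor(hvl_al_mm: float, t_assumed: float,
                                t_true: float, dgn: DgNTable | None = None,
                                al_table: AlAttenuationTable | None = None,
                                glandularity: float = 0.5,
                                energy_equivalent: float | None = None) -> float:
    """Correction factor for an MGD reported at a wrong breast thickness.

    The beam quality (aluminum HVL) is mapped to an effective
    monoenergy; the factor is ``DgN(E_eq, t_true) / DgN(E_eq,
    t_assumed)`` and multiplies the reported MGD.  Passing
    ``energy_equivalent`` skips the HVL inversion.
    """
    if dgn is None:
        dgn = load_dgn_table()
    if energy_equivalent is None:
        if al_table is None:
            al_table = load_al_attenuation()
        energy_equivalent = al_table.effective_energy(hvl_al_mm)
    num = float(dgn(energy_equivalent, t_true, glandularity))
    den = float(dgn(energy_equivalent, t_assumed, glandularity))
    return num / den


def exposure_time_for_mgd(target_mgd: float, spectrum: Spectrum,
                          thickness: float, glandularity: float,
                          mu_en: MuEnTable | None = None,
                          dgn: DgNTable | None = None) -> float:
    """Exposure time (s) that delivers a target MGD at constant dose rate."""
    if target_mgd < 0:
        raise InvalidInputError("target_mgd must be non-negative")
    kerma, _ = air_kerma(spectrum, 1.0, mu_en)
    rate = mean_glandular_dose(kerma, spectrum.bin_centers, thickness,
                               glandularity, dgn)
    if rate <= 0:
        raise InvalidInputError("dose rate is zero; cannot plan exposure")
    return target_mgd / rate


@dataclass(frozen=True)
class CounterCalibration:
    """Scintillation-counter calibration against computed air kerma."""

    counts_per_mgy: float

    def kerma_for_counts(self, counts) -> np.ndarray:
        """Air kerma (mGy) for logged counts; round-trip exact."""
        return np.asarray(counts, dtype=float) / self.counts_per_mgy

    def frame_log_kerma(self, frame_counts) -> tuple[np.ndarray, float]:
        """Per-frame kerma and session total from a frame count log."""
        per_frame = self.kerma_for_counts(frame_counts)
        return per_frame, float(per_frame.sum())


def calibrate_counter(counter_counts_per_s: float,
                      computed_kerma_rate: float) -> CounterCalibration:
    """Calibrate a photon counter to the computed air-kerma rate."""
    if computed_kerma_rate <= 0:
        raise InvalidInputError("kerma rate must be positive")
    if counter_counts_per_s < 0:
        raise InvalidInputError("counter rate must be non-negative")
    return CounterCalibration(counter_counts_per_s / computed_kerma_rate)
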