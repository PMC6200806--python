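"""Inverse-Compton x-ray source model.

A compact synchrotron source produces quasi-monochromatic x-rays by
colliding a stored relativistic electron bunch with an infrared laser
pulse.  For head-on collision and backscattering the emitted photon
energy is

    E_x = 4 * gamma**2 * E_L,      gamma = E_e / E_0,

with ``E_e`` the total electron energy, ``E_0`` the electron rest energy
and ``E_L`` the laser photon energy.  The beam is collimated to a
milliradian-scale cone, so the footprint at the sample grows linearly
with distance and the sample-plane fluence rate follows from the total
flux divided by the footprint area.

The spectrum container deliberately stores *sample-plane fluence rate*
(photons / mm^2 / s per energy bin) rather than source flux, because the
dosimetry chain consumes fluence at the sample position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import ELECTRON_REST_ENERGY_MEV
from .errors import InvalidInputError

__all__ = [
    "SourceConfig",
    "Spectrum",
    "compton_xray_energy",
    "electron_energy_for",
    "make_spectrum",
    "beam_footprint",
    "sample_plane_fluence_rate",
]


@dataclass(frozen=True)
class SourceConfig:
    """Inverse-Compton source settings.

    Parameters
    ----------
    electron_total_energy : float
        Total electron energy E_e in MeV.
    laser_photon_energy : float
        Laser photon energy E_L in eV.
    cone_angle : float
        Full opening angle of the collimated x-ray cone in mrad
        (horizontal axis if ``cone_angle_vertical`` is given).
    sample_distance : float
        Distance from the interaction point to the sample plane in m.
    cone_angle_vertical : float, optional
        Vertical opening angle in mrad for an elliptic beam; defaults to
        ``cone_angle`` (circular cone).
    electron_rest_energy : float
        Electron rest energy in MeV; fixed physical constant.
    """

    electron_total_energy: float
    laser_photon_energy: float
    cone_angle: float = 4.0
    sample_distance: float = 16.0
    cone_angle_vertical: float | None = None
    electron_rest_energy: float = ELECTRON_REST_ENERGY_MEV

    def __post_init__(self) -> None:
        for name in ("electron_total_energy", "laser_photon_energy",
                     "cone_angle", "sample_distance", "electron_rest_energy"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        if self.electron_total_energy <= self.electron_rest_energy:
            raise InvalidInputError(
                "electron_total_energy must exceed the rest energy")
        vmax = self.cone_angle_vertical if self.cone_angle_vertical is not None else 0.0
        if self.cone_angle > 10.0 or vmax > 10.0:
            raise InvalidInputError("cone angles above 10 mrad are not supported")
        if self.cone_angle_vertical is not None and self.cone_angle_vertical <= 0:
            raise InvalidInputError("cone_angle_vertical must be positive")

    @property
    def gamma(self) -> float:
        """Lorentz factor E_e / E_0."""
        return self.electron_total_energy / self.electron_rest_energy


@dataclass
class Spectrum:
    """Binned photon fluence rate at the sample plane.

    Attributes
    ----------
    bin_centers : ndarray
        Bin-center energies in keV, strictly ascending.
    bin_width : float
        Common bin width in keV (> 0).
    fluence_rate : ndarray
        Photons / mm^2 / s reaching the sample plane, per bin.
    """

    bin_centers: np.ndarray
    bin_width: float
    fluence_rate: np.ndarray

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.fluence_rate = np.asarray(self.fluence_rate, dtype=float)
        if self.bin_centers.ndim != 1 or self.bin_centers.size == 0:
            raise InvalidInputError("spectrum needs at least one bin")
        if self.bin_centers.size != self.fluence_rate.size:
            raise InvalidInputError("bin_centers and fluence_rate differ in length")
        if self.bin_width <= 0:
            raise InvalidInputError("bin_width must be positive")
        if np.any(np.diff(self.bin_centers) <= 0):
            raise InvalidInputError("bin_centers must be strictly ascending")
        if np.any(self.fluence_rate < 0):
            raise InvalidInputError("fluence_rate must be non-negative")

    @property
    def total_fluence_rate(self) -> float:
        """Total photons / mm^2 / s summed over bins."""
        return float(self.fluence_rate.sum())

    @property
    def mean_energy(self) -> float:
        """Fluence-weighted mean energy in keV."""
        total = self.total_fluence_rate
        if total == 0:
            return float(np.mean(self.bin_centers))
        return float(np.sum(self.bin_centers * self.fluence_rate) / total)

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "energy_keV": self.bin_centers,
            "fluence_rate_per_mm2_s": self.fluence_rate,
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Spectrum":
        df = pd.read_csv(path)
        centers = df["energy_keV"].to_numpy(float)
        width = float(centers[1] - centers[0]) if centers.size > 1 else max(
            1e-3, 0.01 * centers[0])
        return cls(centers, width, df["fluence_rate_per_mm2_s"].to_numpy(float))


def compton_xray_energy(source: SourceConfig) -> float:
    """Backscattered x-ray energy E_x = 4 gamma^2 E_L, in keV."""
    gamma = source.gamma
    return 4.0 * gamma * gamma * source.laser_photon_energy * 1.0e-3


def electron_energy_for(target_xray_kev: float, laser_ev: float,
                        rest_energy_mev: float = ELECTRON_REST_ENERGY_MEV) -> float:
    """Total electron energy (MeV) that produces a given x-ray energy.

    Inverse of :func:`compton_xray_energy`:
    gamma = sqrt(E_x / (4 E_L)), E_e = gamma * E_0.
    """
    if target_xray_kev <= 0 or laser_ev <= 0:
        raise InvalidInputError("energies must be positive")
    gamma = math.sqrt(target_xray_kev * 1.0e3 / (4.0 * laser_ev))
    return gamma * rest_energy_mev


def beam_footprint(source: SourceConfig) -> tuple[float, float]:
    """Beam footprint (width, height) in mm at the sample plane.

    Small-angle geometry: extent = distance * cone angle per axis.  A
    circular cone gives equal axes; the vertical angle may differ for an
    elliptic beam.
    """
    width = source.sample_distance * source.cone_angle  # m * mrad = mm
    v = source.cone_angle_vertical
    height = source.sample_distance * (v if v is not None else source.cone_angle)
    return (width, height)


def sample_plane_fluence_rate(source: SourceConfig, total_flux: float) -> float:
    """Average fluence rate (photons / mm^2 / s) for a given total flux.

    Divides the source flux (photons / s) by the elliptic footprint area;
    the beam profile is treated as uniform across the collimated cone.
    """
    if total_flux < 0:
        raise InvalidInputError("total_flux must be non-negative")
    w, h = beam_footprint(source)
    area = math.pi * (w / 2.0) * (h / 2.0)
    return total_flux / area


def make_spectrum(peak: float, relative_bandwidth: float,
                  total_fluence_rate: float, n_bins: int) -> Spectrum:
    """Quasi-monochromatic spectrum with a Gaussian profile.

    Parameters
    ----------
    peak : float
        Peak energy in keV.
    relative_bandwidth : float
        FWHM / peak of the line, in [0, 0.2].  ``0`` (or ``n_bins=1``)
        gives the strictly monochromatic limit as a single bin.
    total_fluence_rate : float
        Photons / mm^2 / s summed over all bins.
    n_bins : int
        Number of energy bins (>= 1) spanning +-3 sigma.

    The bin weights are the Gaussian density at the bin centers,
    renormalised so the bin sum equals ``total_fluence_rate`` exactly.
    """
    if n_bins < 1:
        raise InvalidInputError("n_bins must be >= 1")
    if peak <= 0:
        raise InvalidInputError("peak energy must be positive")
    if total_fluence_rate < 0:
        raise InvalidInputError("total_fluence_rate must be non-negative")
    if not (0.0 <= relative_bandwidth <= 0.2):
        raise InvalidInputError("relative_bandwidth must lie in [0, 0.2]")

    sigma = peak * relative_bandwidth / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    if n_bins == 1 or sigma == 0.0:
        width = max(6.0 * sigma, 1e-3 * peak)
        return Spectrum(np.array([peak]), width, np.array([total_fluence_rate]))

    half_span = 3.0 * sigma
    width = 2.0 * half_span / n_bins
    centers = peak - half_span + (np.arange(n_bins) + 0.5) * width
    weights = np.exp(-0.5 * ((centers - peak) / sigma) ** 2)
    weights /= weights.sum()
    return Spectrum(centers, width, total_fluence_rate * weights)
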