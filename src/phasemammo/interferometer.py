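"""Forward model of a two-grating Talbot interferometer.

The phase grating (period ``p1``) imprints a periodic phase modulation
on the beam; at a fractional Talbot distance downstream an intensity
fringe pattern forms and is sampled by scanning the analyzer grating
(period ``p2``) in sub-period steps ("phase stepping").  Each detector
pixel then records a sinusoidal stepping curve

    N_s = (F / n) * T * [1 + V_r * D * cos(theta_s + phi0 + dphi)],

where ``F`` is the open-beam photon count for the full exposure, ``T``
the sample transmission, ``V_r`` the reference fringe visibility, ``D``
the dark-field visibility reduction ``exp(-projected_scatter)`` from
small-angle scattering, and ``dphi`` the fringe-phase shift produced by
refraction in the sample.  A refraction angle ``alpha`` displaces the
fringe pattern by ``alpha * d`` at the analyzer, i.e. by
``2 pi d / p2 * alpha`` in stepping phase, with ``alpha`` given by the
transverse gradient of the wavefront phase.

Counting statistics are Poisson; energy bins of the spectrum are
simulated independently and their expected counts summed before noise
is drawn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import wavelength_m
from .errors import InvalidInputError
from .phantom import PhantomModel, project
from .source import Spectrum

__all__ = [
    "InterferometerConfig",
    "SteppingStack",
    "talbot_distance",
    "angular_sensitivity",
    "refraction_fringe_shift",
    "simulate_stepping_stack",
    "simulate_plain_radiograph",
]


@dataclass(frozen=True)
class InterferometerConfig:
    """Two-grating interferometer geometry and acquisition settings.

    ``phase_shift_type`` selects a pi/2- or pi-shifting phase grating;
    the fractional Talbot distances differ by a factor of four.  The
    default geometry (p1 = 4.9 um, p2 = 5.0 um, first Talbot order,
    pi/2 grating at 25 keV) yields an inter-grating distance of ~24 cm.
    """

    p1: float = 4.9                     # um
    p2: float = 5.0                     # um
    inter_grating_distance: float = 0.25  # m
    design_energy: float = 25.0         # keV
    phase_shift_type: str = "pi_half"
    talbot_order: int = 1
    n_steps: int = 8
    reference_visibility: float = 0.45

    def __post_init__(self) -> None:
        if self.p1 <= 0 or self.p2 <= 0:
            raise InvalidInputError("grating periods must be positive")
        if self.inter_grating_distance <= 0 or self.design_energy <= 0:
            raise InvalidInputError("distance and design energy must be positive")
        if self.phase_shift_type not in ("pi_half", "pi"):
            raise InvalidInputError("phase_shift_type must be 'pi_half' or 'pi'")
        if self.talbot_order < 1:
            raise InvalidInputError("talbot_order must be a positive integer")
        if self.n_steps < 3:
            raise InvalidInputError("phase stepping needs at least 3 steps")
        if not (0.0 < self.reference_visibility <= 1.0):
            raise InvalidInputError("reference_visibility must lie in (0, 1]")

    @property
    def step_phases(self) -> np.ndarray:
        """Uniform analyzer step phases over one p2 period, radians."""
        return 2.0 * math.pi * np.arange(self.n_steps) / self.n_steps


@dataclass
class SteppingStack:
    """Photon-count images for each analyzer step.

    ``counts`` has shape (n_steps, rows, cols); ``step_phases`` are the
    analyzer positions expressed as fractions of one p2 period in
    radians, strictly increasing within [0, 2 pi).
    """

    counts: np.ndarray
    step_phases: np.ndarray
    exposure_per_step: float
    pixel_pitch: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.step_phases = np.asarray(self.step_phases, dtype=float)
        if self.counts.ndim != 3:
            raise InvalidInputError("counts must be (n_steps, rows, cols)")
        if self.counts.shape[0] != self.step_phases.size:
            raise InvalidInputError("one step phase per counts page required")
        if self.step_phases.size < 3:
            raise InvalidInputError("at least 3 steps required")
        if np.any(np.diff(self.step_phases) <= 0) or np.any(
                self.step_phases < 0) or self.step_phases[-1] >= 2 * math.pi:
            raise InvalidInputError("step_phases must be strictly increasing in [0, 2pi)")
        if np.any(self.counts < 0):
            raise InvalidInputError("counts must be non-negative")
        if self.exposure_per_step <= 0 or self.pixel_pitch <= 0:
            raise InvalidInputError("exposure and pixel pitch must be positive")

    @property
    def n_steps(self) -> int:
        return self.counts.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.counts.shape[1:]


def talbot_distance(config: InterferometerConfig) -> float:
    """Fractional Talbot design distance in metres.

    ``d = m p1^2 / (2 lambda)`` for a pi/2 grating and
    ``d = m p1^2 / (8 lambda)`` for a pi grating, order ``m``.
    """
    lam = wavelength_m(config.design_energy)
    p1_m = config.p1 * 1e-6
    denom = 2.0 if config.phase_shift_type == "pi_half" else 8.0
    return config.talbot_order * p1_m**2 / (denom * lam)


def angular_sensitivity(config: InterferometerConfig,
                        energy: float | None = None) -> float:
    """Stepping-phase shift per radian of refraction angle: 2 pi d / p2.

    Geometric: a refraction angle alpha displaces the fringe by
    ``alpha * d`` at the analyzer plane, which is ``alpha * d / p2``
    periods.  Independent of energy for a fixed geometry; the ``energy``
    argument is accepted for interface uniformity.
    """
    del energy
    return 2.0 * math.pi * config.inter_grating_distance / (config.p2 * 1e-6)


def refraction_fringe_shift(phase_map: np.ndarray, pixel_pitch_mm: float,
                            config: InterferometerConfig,
                            energy: float) -> np.ndarray:
    """Fringe-phase shift map (radians) from a wavefront phase map.

    The refraction angle is ``alpha = (lambda / 2 pi) * dPhi/dx`` with
    the transverse derivative taken by central finite differences along
    the column axis over the pixel pitch; positive shift corresponds to
    refraction toward increasing column index.
    """
    lam = wavelength_m(energy)
    pitch_m = pixel_pitch_mm * 1e-3
    dphi_dx = np.gradient(phase_map, axis=1) / pitch_m
    alpha = lam / (2.0 * math.pi) * dphi_dx
    return angular_sensitivity(config) * alpha


def _resolve_maps(maps, spectrum: Spectrum, pixel_pitch: float | None):
    """Normalise the `maps` argument to a per-bin map provider."""
    if isinstance(maps, PhantomModel):
        phantom = maps
        pitch = phantom.pixel_pitch

        def at_energy(e: float):
            if spectrum.bin_centers.size == 1 and math.isclose(
                    e, phantom.reference_energy):
                return phantom.maps()
            return project(phantom, e)

        return at_energy, pitch, phantom.shape
    att, phase, scat = (np.asarray(m, dtype=float) for m in maps)
    if not (att.shape == phase.shape == scat.shape):
        raise InvalidInputError("maps must share one shape")
    if pixel_pitch is None:
        raise InvalidInputError("pixel_pitch is required with raw maps")
    return (lambda e: (att, phase, scat)), pixel_pitch, att.shape


def simulate_stepping_stack(maps, config: InterferometerConfig,
                            spectrum: Spectrum, exposure_total: float,
                            seed: int | None = 0, with_sample: bool = True,
                            noise: bool = True,
                            pixel_pitch: float | None = None,
                            reference_phase: np.ndarray | float = 0.0,
                            ) -> SteppingStack:
    """Synthesise a phase-stepping stack.

    Parameters
    ----------
    maps : PhantomModel or (attenuation, phase, scatter) arrays
        Projected sample maps.  A ``PhantomModel`` is re-projected to
        each energy bin; raw arrays are used as-is for every bin.
    exposure_total : float
        Total exposure in seconds, split evenly over the steps.
    with_sample : bool
        ``False`` produces the reference (open-beam) scan: T = 1, D = 1
        and no refraction shift.
    noise : bool
        Draw Poisson counts when ``True``; return expected counts
        otherwise.
    reference_phase : array or float
        Reference fringe phase phi0 (flat by default; an array models a
        slowly varying moire background).
    """
    if exposure_total <= 0:
        raise InvalidInputError("exposure_total must be positive")
    at_energy, pitch, shape = _resolve_maps(maps, spectrum, pixel_pitch)

    theta = config.step_phases
    pixel_area = pitch * pitch  # mm^2
    expected = np.zeros((config.n_steps,) + shape)
    phi0 = np.broadcast_to(np.asarray(reference_phase, dtype=float), shape)

    for e, rate in zip(spectrum.bin_centers, spectrum.fluence_rate):
        if rate == 0:
            continue
        fluence = rate * pixel_area * exposure_total  # photons per pixel
        if with_sample:
            att, phase, scat = at_energy(e)
            trans = np.exp(-att)
            dark = np.exp(-scat)
            dphi = refraction_fringe_shift(phase, pitch, config, e)
        else:
            trans = np.ones(shape)
            dark = np.ones(shape)
            dphi = np.zeros(shape)
        carrier = config.reference_visibility * dark
        for s, th in enumerate(theta):
            expected[s] += (fluence / config.n_steps) * trans * (
                1.0 + carrier * np.cos(th + phi0 + dphi))

    expected = np.clip(expected, 0.0, None)
    if noise:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected
    return SteppingStack(counts, theta, exposure_total / config.n_steps, pitch)


def simulate_plain_radiograph(maps, spectrum: Spectrum, exposure_total: float,
                              seed: int | None = 0, noise: bool = True,
                              pixel_pitch: float | None = None) -> np.ndarray:
    """Grating-free absorption radiograph (photon counts per pixel).

    Expected counts are ``F * T`` per energy bin, summed over bins, then
    Poisson-sampled.  This is the monochromatic absorption-contrast arm
    of the dose study.
    """
    if exposure_total <= 0:
        raise InvalidInputError("exposure_total must be positive")
    at_energy, pitch, shape = _resolve_maps(maps, spectrum, pixel_pitch)
    pixel_area = pitch * pitch
    expected = np.zeros(shape)
    for e, rate in zip(spectrum.bin_centers, spectrum.fluence_rate):
        if rate == 0:
            continue
        att, _, _ = at_energy(e)
        expected += rate * pixel_area * exposure_total * np.exp(-att)
    if noise:
        rng = np.random.default_rng(seed)
        return rng.poisson(expected).astype(float)
    return expected
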