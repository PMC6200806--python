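"""Phase-stepping retrieval of transmission, differential phase, dark field.

Each pixel's stepping curve ``N_s = a0 (1 + V cos(theta_s + phi))`` is
decomposed into its mean ``a0`` and first discrete Fourier harmonic
``(a1, phi1)``.  For uniform steps covering exactly one analyzer period
the DFT estimator coincides with the least-squares three-parameter
sinusoid fit and is exact for noiseless data.  The three image channels
follow from sample / reference ratios:

* transmission      T   = a0_sample / a0_reference
* differential phase dphi = wrap(phi1_sample - phi1_reference)
* dark field        DF  = (a1/a0)_sample / (a1/a0)_reference

Sign convention: positive differential phase corresponds to refraction
toward increasing column index (matching the forward model).  Pixels
where the decomposition is degenerate (zero mean, or vanishing first
harmonic so the phase is undefined) are flagged in an explicit validity
mask instead of carrying sentinel values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .interferometer import SteppingStack

__all__ = [
    "MultimodalImage",
    "fit_stepping_curve",
    "multimodal_retrieve",
    "visibility_map",
    "median_visibility",
    "wrap_phase",
]

_AMPLITUDE_EPS = 1e-12  # relative a1/a0 below which phase is undefined


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles into (-pi, pi]; idempotent."""
    return math.pi - np.mod(math.pi - np.asarray(phi, dtype=float),
                            2.0 * math.pi)


@dataclass
class MultimodalImage:
    """Retrieved transmission / differential-phase / dark-field channels.

    ``valid`` marks pixels where all three channels are defined.  The
    dark-field channel is the sample/reference visibility ratio (not its
    logarithm); use :meth:`log_dark_field` for the additive form.
    """

    transmission: np.ndarray
    differential_phase: np.ndarray
    dark_field: np.ndarray
    pixel_pitch: float
    valid: np.ndarray
    provenance: dict | None = None

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.transmission, self.differential_phase,
                                    self.dark_field, self.valid)}
        if len(shapes) != 1:
            raise InvalidInputError("channel shapes differ")
        if self.pixel_pitch <= 0:
            raise InvalidInputError("pixel_pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.transmission.shape

    def log_dark_field(self) -> np.ndarray:
        """-ln(DF): the projected small-angle scattering power."""
        out = np.full(self.shape, np.nan)
        ok = self.valid & (self.dark_field > 0)
        out[ok] = -np.log(self.dark_field[ok])
        return out

    def channel(self, name: str) -> np.ndarray:
        table = {"transmission": self.transmission,
                 "differential_phase": self.differential_phase,
                 "dark_field": self.dark_field}
        try:
            return table[name]
        except KeyError:
            raise InvalidInputError(f"unknown channel {name!r}") from None


def fit_stepping_curve(stack: SteppingStack
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel (a0, a1, phi1, valid) from a stepping stack.

    ``a0`` is the step mean; ``a1`` and ``phi1`` are amplitude and phase
    of the first discrete Fourier harmonic over the (uniform, single
    period) step grid.  ``valid`` is False where ``a0 <= 0`` or the
    relative modulation is numerically zero (phase undefined); such
    pixels are never silently divided.
    """
    counts = stack.counts
    n = stack.n_steps
    theta = stack.step_phases
    a0 = counts.mean(axis=0)
    phasor = (2.0 / n) * np.tensordot(np.exp(-1j * theta), counts, axes=(0, 0))
    a1 = np.abs(phasor)
    phi1 = np.angle(phasor)
    with np.errstate(invalid="ignore", divide="ignore"):
        valid = (a0 > 0) & (a1 > _AMPLITUDE_EPS * np.maximum(a0, _AMPLITUDE_EPS))
    return a0, a1, phi1, valid


def visibility_map(stack: SteppingStack) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel fringe visibility a1/a0 and its validity mask."""
    a0, a1, _, valid = fit_stepping_curve(stack)
    vis = np.full(a0.shape, np.nan)
    vis[valid] = a1[valid] / a0[valid]
    return vis, valid


def median_visibility(stack: SteppingStack) -> float:
    """Median visibility over valid pixels (scalar summary)."""
    vis, valid = visibility_map(stack)
    if not np.any(valid):
        raise InvalidInputError("no valid pixels for visibility estimate")
    return float(np.median(vis[valid]))


def multimodal_retrieve(sample: SteppingStack,
                        reference: SteppingStack) -> MultimodalImage:
    """Ratio-based multimodal retrieval from sample and reference stacks."""
    if sample.image_shape != reference.image_shape:
        raise InvalidInputError("sample and reference image shapes differ")
    if sample.n_steps != reference.n_steps or not np.allclose(
            sample.step_phases, reference.step_phases):
        raise InvalidInputError("sample and reference step grids differ")

    a0_s, a1_s, phi_s, ok_s = fit_stepping_curve(sample)
    a0_r, a1_r, phi_r, ok_r = fit_stepping_curve(reference)
    valid = ok_s & ok_r

    trans = np.full(a0_s.shape, np.nan)
    dphi = np.full(a0_s.shape, np.nan)
    dark = np.full(a0_s.shape, np.nan)
    trans[valid] = a0_s[valid] / a0_r[valid]
    dphi[valid] = wrap_phase(phi_s[valid] - phi_r[valid])
    dark[valid] = (a1_s[valid] / a0_s[valid]) / (a1_r[valid] / a0_r[valid])

    return MultimodalImage(
        trans, dphi, dark, sample.pixel_pitch, valid,
        provenance={"n_steps": sample.n_steps,
                    "exposure_per_step_s": sample.exposure_per_step},
    )
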