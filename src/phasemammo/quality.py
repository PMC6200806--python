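"""Image-quality metrics: CNR, power-spectrum resolution, ACR scoring.

Contrast-to-noise ratio between two regions of interest:

    CNR = (S1_mean - S2_mean) / sigma_BG,

with the noise term the sample standard deviation (n-1 denominator) of
a larger object-free background ROI.

Spatial resolution is estimated from the image power spectrum: the
squared modulus of the 2-D Fourier transform is Gaussian-smoothed and
radially averaged; the noise baseline is the median smoothed power in
the top decile of frequencies below Nyquist; the resolution is the
maximal spatial frequency (cycles/mm = line pairs/mm) at which the
radial power crosses down through twice that baseline.  When the
criterion finds no crossing (pure noise, or a noiseless image with no
flat baseline) the estimator signals "undetermined" instead of
fabricating a number.

ACR-style accreditation scoring counts, per object category, the test
objects whose CNR magnitude reaches the Rose-style detectability
threshold |CNR| >= 1; the phantom passes if at least 4 fibers, 3
microcalcification groups and 3 masses are resolved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InvalidInputError, UndefinedCnrError, UndeterminedResolutionError
from .phantom import PhantomModel, RoiSpec, TestObject
from .retrieval import MultimodalImage

__all__ = [
    "CnrResult",
    "ResolutionResult",
    "AcrScore",
    "cnr",
    "power_spectrum_resolution",
    "acr_score",
    "phantom_quality_table",
    "ACR_REQUIRED",
    "DETECTABILITY_THRESHOLD",
]

ACR_REQUIRED = {"fiber": 4, "calcification_group": 3, "mass": 3}
"""Minimum resolved objects per category for an accreditation pass."""

DETECTABILITY_THRESHOLD = 1.0
"""Rose-style |CNR| threshold below which an object is not detectable."""


@dataclass(frozen=True)
class CnrResult:
    """CNR between two ROIs with its ingredients."""

    cnr: float
    mean_roi1: float
    mean_roi2: float
    sigma_bg: float
    roi1: RoiSpec
    roi2: RoiSpec
    roi_bg: RoiSpec


@dataclass(frozen=True)
class ResolutionResult:
    """Power-spectrum resolution estimate in line pairs per mm."""

    resolution: float
    uncertainty: float
    nyquist: float
    filter_sigma: float
    baseline_fraction: float
    threshold_factor: float


@dataclass(frozen=True)
class AcrScore:
    """Accreditation outcome: resolved-object counts and pass flag."""

    resolved: dict
    passed: bool
    required: dict = field(default_factory=lambda: dict(ACR_REQUIRED))


def cnr(image: np.ndarray, roi1: RoiSpec, roi2: RoiSpec,
        roi_bg: RoiSpec) -> CnrResult:
    """Contrast-to-noise ratio between ``roi1`` and ``roi2``.

    ``roi_bg`` must be larger than both object ROIs; its sample standard
    deviation (ddof=1) supplies the noise term.  A zero-variance
    background raises :class:`UndefinedCnrError`.
    """
    image = np.asarray(image, dtype=float)
    for roi in (roi1, roi2, roi_bg):
        if not roi.within(image.shape):
            raise InvalidInputError("ROI outside image")
    if roi_bg.area <= max(roi1.area, roi2.area):
        raise InvalidInputError("background ROI must be larger than object ROIs")
    m1 = float(roi1.extract(image).mean())
    m2 = float(roi2.extract(image).mean())
    sigma = float(roi_bg.extract(image).std(ddof=1))
    if sigma == 0.0 or not np.isfinite(sigma):
        raise UndefinedCnrError("background ROI has zero variance")
    return CnrResult((m1 - m2) / sigma, m1, m2, sigma, roi1, roi2, roi_bg)


def _radial_power(image: np.ndarray, pixel_pitch: float,
                  filter_sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Radially averaged, Gaussian-smoothed power spectrum.

    Returns (frequencies in cycles/mm, mean smoothed power per annulus),
    excluding the DC bin.
    """
    img = np.asarray(image, dtype=float)
    img = img - img.mean()
    # Hann window suppresses leakage from non-periodic image content,
    # which would otherwise lift the on-axis spectral tail and corrupt
    # the noise-baseline estimate
    win = np.outer(np.hanning(img.shape[0]), np.hanning(img.shape[1]))
    power = np.abs(np.fft.fft2(img * win)) ** 2
    power = ndimage.gaussian_filter(np.fft.fftshift(power), filter_sigma,
                                    mode="nearest")
    fr = np.fft.fftshift(np.fft.fftfreq(img.shape[0], d=pixel_pitch))
    fc = np.fft.fftshift(np.fft.fftfreq(img.shape[1], d=pixel_pitch))
    radius = np.hypot(fr[:, None], fc[None, :])
    df = 1.0 / (min(img.shape) * pixel_pitch)  # annulus width, cycles/mm
    idx = np.round(radius / df).astype(int)
    counts = np.bincount(idx.ravel())
    sums = np.bincount(idx.ravel(), weights=power.ravel())
    with np.errstate(invalid="ignore"):
        profile = sums / counts
    freqs = np.arange(profile.size) * df
    return freqs[1:], profile[1:]


def _resolution_single(image: np.ndarray, pixel_pitch: float,
                       filter_sigma: float, baseline_fraction: float,
                       threshold_factor: float) -> float:
    nyquist = 1.0 / (2.0 * pixel_pitch)
    full_freqs, full_profile = _radial_power(image, pixel_pitch, filter_sigma)
    in_band = full_freqs <= nyquist
    freqs, profile = full_freqs[in_band], full_profile[in_band]
    if freqs.size < 8:
        raise InvalidInputError("image too small for a spectral estimate")
    tail = freqs >= (1.0 - baseline_fraction) * nyquist
    baseline = float(np.median(profile[tail]))
    if baseline <= 0 or not np.isfinite(baseline):
        raise UndeterminedResolutionError("no noise baseline (flat spectrum tail)")
    # the baseline is only a *noise* floor if the spectrum has gone flat:
    # check the corner band just above the Nyquist radius (reachable along
    # the grid diagonals), where white pixel noise keeps the same power but
    # a noiseless spectrum keeps falling
    corner = (full_freqs > 1.02 * nyquist) & (full_freqs <= 1.35 * nyquist)
    corner_level = float(np.median(full_profile[corner]))
    if not np.isfinite(corner_level) or corner_level < baseline / 1.25:
        raise UndeterminedResolutionError(
            "spectrum still falling at Nyquist: no flat noise floor")
    threshold = threshold_factor * baseline

    above = profile >= threshold
    crossings = np.flatnonzero(above[:-1] & ~above[1:])
    if crossings.size == 0:
        raise UndeterminedResolutionError(
            "radial power never crosses down through the threshold")
    i = int(crossings[-1])  # maximal frequency crossing
    # linear interpolation between the bracketing annuli
    p0, p1 = profile[i], profile[i + 1]
    frac = (p0 - threshold) / (p0 - p1) if p0 != p1 else 0.0
    estimate = float(freqs[i] + frac * (freqs[i + 1] - freqs[i]))
    if estimate >= (1.0 - baseline_fraction) * nyquist:
        # the signal is still above the "noise" inside the band that
        # defined the baseline: there is no real noise floor (e.g. a
        # noiseless image whose spectrum falls through the whole band)
        raise UndeterminedResolutionError(
            "threshold crossing lies inside the noise-baseline band")
    return estimate


def power_spectrum_resolution(image: np.ndarray, pixel_pitch: float,
                              filter_sigma: float = 0.5,
                              baseline_fraction: float = 0.1,
                              threshold_factor: float = 2.0
                              ) -> ResolutionResult:
    """Resolution (LP/mm) from the 2x-noise-baseline spectral criterion.

    Parameters
    ----------
    image : ndarray
        At least 64 x 64 pixels.
    pixel_pitch : float
        Pixel pitch in mm.
    filter_sigma : float
        Gaussian smoothing width applied to the 2-D power spectrum, in
        frequency bins.
    baseline_fraction : float
        Fraction of the band below Nyquist (taken from the top) whose
        median smoothed power defines the noise baseline.
    threshold_factor : float
        Signal-over-baseline factor defining the resolution criterion.

    The quoted uncertainty is the standard deviation of the estimate
    over the four image quadrants (quadrants without a determined
    estimate are skipped).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 64:
        raise InvalidInputError("image must be 2-D and at least 64x64")
    if pixel_pitch <= 0:
        raise InvalidInputError("pixel_pitch must be positive")

    estimate = _resolution_single(image, pixel_pitch, filter_sigma,
                                  baseline_fraction, threshold_factor)

    h, w = image.shape
    quadrant_estimates = []
    for rs in (slice(0, h // 2), slice(h // 2, h)):
        for cs in (slice(0, w // 2), slice(w // 2, w)):
            try:
                quadrant_estimates.append(_resolution_single(
                    image[rs, cs], pixel_pitch, filter_sigma,
                    baseline_fraction, threshold_factor))
            except (UndeterminedResolutionError, InvalidInputError):
                continue
    uncertainty = (float(np.std(quadrant_estimates))
                   if len(quadrant_estimates) >= 2 else float("nan"))
    return ResolutionResult(estimate, uncertainty,
                            1.0 / (2.0 * pixel_pitch), filter_sigma,
                            baseline_fraction, threshold_factor)


def acr_score(objects: list[tuple[TestObject, "CnrResult | float"]]) -> AcrScore:
    """Score accreditation-phantom detectability from per-object CNRs.

    An object is resolved iff |CNR| >= 1 (attenuating objects have
    negative signed CNR on count images; the magnitude carries the
    detectability).  Pass requires at least 4 fibers, 3 calcification
    groups and 3 masses resolved.
    """
    seen = set()
    resolved = {cat: 0 for cat in ACR_REQUIRED}
    for obj, result in objects:
        key = (obj.category, obj.rank)
        if key in seen:
            raise InvalidInputError(f"duplicate object {key}")
        seen.add(key)
        value = result.cnr if isinstance(result, CnrResult) else float(result)
        if abs(value) >= DETECTABILITY_THRESHOLD:
            resolved[obj.category] = resolved.get(obj.category, 0) + 1
    passed = all(resolved.get(cat, 0) >= need
                 for cat, need in ACR_REQUIRED.items())
    return AcrScore(resolved, passed)


def _image_channels(entry) -> list[tuple[str, np.ndarray]]:
    """Expand an input image into named scalar channels for scoring.

    Differential phase is excluded: its signal is differential, so a
    mean-difference CNR is not meaningful.
    """
    if isinstance(entry, MultimodalImage):
        return [("transmission", entry.transmission),
                ("dark_field", entry.dark_field)]
    return [("absorption", np.asarray(entry, dtype=float))]


def phantom_quality_table(images, phantom: PhantomModel,
                          resolution_kwargs: dict | None = None) -> pd.DataFrame:
    """Batch CNR + resolution table for a set of phantom images.

    Parameters
    ----------
    images : list of (modality, mgd_mgy, image)
        ``image`` may be a plain 2-D count image or a
        :class:`MultimodalImage` (expanded into transmission and
        dark-field channels).
    phantom : PhantomModel
        Supplies the object layout, each object's paired background ROI
        and the large background ROI used for the noise term.

    Returns a tidy frame with one row per (modality, channel, object)
    holding the |CNR|, plus one row per (modality, channel) with the
    power-spectrum resolution (NaN where the criterion is undetermined).
    """
    if phantom.background_roi is None:
        raise InvalidInputError("phantom has no global background ROI")
    if not phantom.layout:
        raise InvalidInputError("phantom has no layout objects")
    resolution_kwargs = resolution_kwargs or {}
    rows = []
    for modality, mgd, entry in images:
        for channel, img in _image_channels(entry):
            if img.shape != phantom.shape:
                raise InvalidInputError(
                    f"image shape {img.shape} does not match phantom "
                    f"{phantom.shape}")
            for obj in phantom.layout:
                res = cnr(img, obj.roi, obj.background_roi,
                          phantom.background_roi)
                rows.append({
                    "modality": modality, "channel": channel,
                    "mgd_mgy": mgd, "row_type": "cnr",
                    "object_category": obj.category, "object_rank": obj.rank,
                    "cnr": abs(res.cnr), "resolution_lp_mm": np.nan,
                    "resolution_unc_lp_mm": np.nan,
                })
            try:
                r = power_spectrum_resolution(img, phantom.pixel_pitch,
                                              **resolution_kwargs)
                res_val, res_unc = r.resolution, r.uncertainty
            except (UndeterminedResolutionError, UndefinedCnrError):
                res_val, res_unc = np.nan, np.nan
            rows.append({
                "modality": modality, "channel": channel, "mgd_mgy": mgd,
                "row_type": "resolution", "object_category": None,
                "object_rank": None, "cnr": np.nan,
                "resolution_lp_mm": res_val,
                "resolution_unc_lp_mm": res_unc,
            })
    return pd.DataFrame(rows)
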