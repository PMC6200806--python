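"""Digital phantoms expressed as projected line-integral maps.

A phantom is stored as three per-pixel maps on a common grid:

* ``projected_attenuation`` — dimensionless integral of the linear
  attenuation coefficient along the beam, so transmission is
  ``exp(-projected_attenuation)``;
* ``projected_phase`` — accumulated wavefront phase (radians) at a
  reference energy, ``(2 pi / lambda) * integral(delta dz)``;
* ``projected_scatter`` — dimensionless small-angle-scattering strength,
  the log of the dark-field visibility reduction, so the fringe
  visibility is multiplied by ``exp(-projected_scatter)``.

Two generators are provided: a mammography accreditation phantom in the
style of the Gammex 156 (fibers, microcalcification speck groups and
masses embedded in a 4.5 cm breast-equivalent slab), and a power-law
textured breast-like phantom with optional inserted lesion.  Both carry
ground-truth object layouts (ROI per object plus a paired background
ROI) so image-quality scoring never depends on manual ROI placement.

ROI convention: 0-based, row-major, half-open on both axes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import InvalidInputError, TableRangeError

__all__ = [
    "RoiSpec",
    "TestObject",
    "PhantomModel",
    "gammex_like_phantom",
    "breast_texture_phantom",
    "project",
    "REFERENCE_ENERGY_KEV",
]

REFERENCE_ENERGY_KEV = 25.0
"""Energy at which phantom maps are stored."""

CATEGORIES = ("fiber", "calcification_group", "mass")

# Linear attenuation (1/cm) of 50/50 glandular/adipose breast-equivalent
# material at the reference energy; matches the shipped material table.
MU_BREAST_5050_25KEV = 0.50
MU_GLANDULAR_25KEV = 0.56
MU_ADIPOSE_25KEV = 0.44

# Per-rank projected-attenuation contrasts (dimensionless, on top of the
# slab) for the accreditation phantom's three object classes.  Calibrated
# once against the default acquisition chain: with the expected
# background counts N_bg of a 2.0 mGy monochromatic absorption image,
# contrast = -ln(1 - CNR_target / sqrt(N_bg)) reproduces a Table-2-like
# CNR pattern (rank-1 objects strong, the smallest mass near the CNR = 1
# detectability limit at clinical dose).
FIBER_CONTRAST = (0.0173, 0.0136, 0.0107, 0.0081, 0.0059, 0.0033)
CALC_CONTRAST = (0.1751, 0.1160, 0.0640, 0.0296, 0.0110)
MASS_CONTRAST = (0.0448, 0.0315, 0.0221, 0.0129, 0.0048)

# Projected small-angle-scatter strengths (dark-field extinction).  The
# speck groups and masses are scatter-dominant (granular microstructure);
# fibers scatter weakly.
FIBER_SCATTER = (0.03, 0.028, 0.026, 0.024, 0.022, 0.02)
CALC_SCATTER = (0.55, 0.45, 0.35, 0.28, 0.22)
MASS_SCATTER = (0.30, 0.28, 0.26, 0.24, 0.22)

# Phase-to-attenuation coupling (delta/beta-like ratio per material
# class); projected phase contribution = 0.5 * ratio * attenuation
# contribution at the reference energy.
PHASE_RATIO = {"breast_tissue": 1000.0, "fiber": 1100.0,
               "calcification": 300.0, "mass": 1050.0}

FIBER_WIDTH_PX = (10, 8, 6, 5, 4, 3)
FIBER_LENGTH_PX = 48
CALC_SPECK_RADIUS_PX = (5, 4, 3, 2, 2)
CALC_RING_RADIUS_PX = 14
MASS_RADIUS_PX = (16, 13, 10, 8, 6)

_CELL = 64  # pixels per layout cell


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular region of interest; 0-based, half-open."""

    row_start: int
    col_start: int
    row_stop: int
    col_stop: int

    def __post_init__(self) -> None:
        if self.row_stop <= self.row_start or self.col_stop <= self.col_start:
            raise InvalidInputError("ROI stop indices must exceed start indices")
        if min(self.row_start, self.col_start) < 0:
            raise InvalidInputError("ROI indices must be non-negative")

    @property
    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row_start, self.row_stop),
                slice(self.col_start, self.col_stop))

    @property
    def area(self) -> int:
        return (self.row_stop - self.row_start) * (self.col_stop - self.col_start)

    def within(self, shape: tuple[int, int]) -> bool:
        return self.row_stop <= shape[0] and self.col_stop <= shape[1]

    def overlaps(self, other: "RoiSpec") -> bool:
        return not (self.row_stop <= other.row_start
                    or other.row_stop <= self.row_start
                    or self.col_stop <= other.col_start
                    or other.col_stop <= self.col_start)

    def extract(self, image: np.ndarray) -> np.ndarray:
        return image[self.slices]


@dataclass(frozen=True)
class TestObject:
    """One scored insert of an accreditation-style phantom.

    ``rank`` orders the objects within a category, 1 = largest/thickest.
    ``roi`` sits fully inside the object; ``background_roi`` is a nearby
    object-free patch used as the comparison region of the CNR.
    """

    category: str
    rank: int
    roi: RoiSpec
    background_roi: RoiSpec

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise InvalidInputError(f"unknown category {self.category!r}")
        if self.rank < 1:
            raise InvalidInputError("rank must be >= 1")
        if self.roi.overlaps(self.background_roi):
            raise InvalidInputError("object ROI overlaps its background ROI")


@dataclass
class PhantomModel:
    """Projected phantom maps plus ground-truth layout.

    ``class_maps`` decomposes the attenuation map into per-material-class
    contributions at the reference energy, enabling energy rescaling in
    :func:`project`.  ``background_roi`` is the large uniform region used
    for the noise term of CNR estimates.
    """

    projected_attenuation: np.ndarray
    projected_phase: np.ndarray
    projected_scatter: np.ndarray
    pixel_pitch: float
    compressed_thickness: float
    layout: list[TestObject] = field(default_factory=list)
    background_roi: RoiSpec | None = None
    reference_energy: float = REFERENCE_ENERGY_KEV
    class_maps: dict[str, np.ndarray] | None = None
    scatter_energy_power: float = 2.0

    def __post_init__(self) -> None:
        a, p, s = (np.asarray(m, dtype=float) for m in
                   (self.projected_attenuation, self.projected_phase,
                    self.projected_scatter))
        if not (a.shape == p.shape == s.shape):
            raise InvalidInputError("phantom maps must share one shape")
        if self.pixel_pitch <= 0:
            raise InvalidInputError("pixel_pitch must be positive")
        if np.any(a < 0) or np.any(s < 0):
            raise InvalidInputError("attenuation and scatter maps must be >= 0")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(p))
                and np.all(np.isfinite(s))):
            raise InvalidInputError("phantom maps must be finite")
        self.projected_attenuation, self.projected_phase, self.projected_scatter = a, p, s
        for obj in self.layout:
            if not (obj.roi.within(a.shape) and obj.background_roi.within(a.shape)):
                raise InvalidInputError("layout ROI outside the image")

    @property
    def shape(self) -> tuple[int, int]:
        return self.projected_attenuation.shape

    def maps(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.projected_attenuation, self.projected_phase,
                self.projected_scatter)

    def objects(self, category: str | None = None) -> list[TestObject]:
        if category is None:
            return list(self.layout)
        return [o for o in self.layout if o.category == category]


def _disc_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _material_table() -> pd.DataFrame:
    with resources.files("phasemammo.data").joinpath("materials_mu.csv").open() as fh:
        return pd.read_csv(fh)


def _inscribed_half(radius: int) -> int:
    return max(1, int(radius / math.sqrt(2.0)))


def gammex_like_phantom(pixel_pitch: float = 0.071, seed: int = 0,
                        contrast_scale: float = 1.0,
                        scatter_scale: float = 1.0) -> PhantomModel:
    """Accreditation phantom: 6 fibers, 5 speck groups, 5 masses.

    The inserts sit in a uniform 4.5 cm breast-equivalent slab (50/50
    glandular/adipose) on a grid of 64 px cells; a bottom strip of plain
    slab provides the large background ROI for noise estimation.  Object
    size and contrast decrease with rank; the default contrasts are the
    module-level calibration constants, jointly scalable through
    ``contrast_scale`` / ``scatter_scale``.

    The construction is fully deterministic; ``seed`` is accepted for
    interface symmetry with the textured generator and ignored.
    """
    if not (0.01 < pixel_pitch < 0.2):
        raise InvalidInputError("pixel_pitch must lie in (0.01, 0.2) mm")
    del seed  # deterministic by construction

    thickness = 4.5
    n_rows, n_cols = 4 * _CELL, 6 * _CELL
    shape = (n_rows, n_cols)
    slab = np.full(shape, MU_BREAST_5050_25KEV * thickness)
    fiber_map = np.zeros(shape)
    calc_map = np.zeros(shape)
    mass_map = np.zeros(shape)
    scatter = np.zeros(shape)
    layout: list[TestObject] = []

    def cell_origin(row_block: int, col_block: int) -> tuple[int, int]:
        return row_block * _CELL, col_block * _CELL

    def cell_background(origin) -> RoiSpec:
        r0, c0 = origin
        return RoiSpec(r0 + 3, c0 + 3, r0 + 15, c0 + 15)

    # --- fibers: vertical bars, row block 0 -------------------------------
    for rank, (width, da, ds) in enumerate(
            zip(FIBER_WIDTH_PX, FIBER_CONTRAST, FIBER_SCATTER), start=1):
        r0, c0 = cell_origin(0, rank - 1)
        top = r0 + (_CELL - FIBER_LENGTH_PX) // 2
        left = c0 + _CELL // 2 - width // 2
        fiber_map[top: top + FIBER_LENGTH_PX, left: left + width] += da * contrast_scale
        scatter[top: top + FIBER_LENGTH_PX, left: left + width] += ds * scatter_scale
        margin = 1 if width >= 4 else 0
        roi = RoiSpec(top + 2, left + margin, top + FIBER_LENGTH_PX - 2,
                      left + width - margin)
        layout.append(TestObject("fiber", rank, roi, cell_background((r0, c0))))

    # --- microcalcification groups: 6 specks each, row block 1 ------------
    for rank, (radius, da, ds) in enumerate(
            zip(CALC_SPECK_RADIUS_PX, CALC_CONTRAST, CALC_SCATTER), start=1):
        r0, c0 = cell_origin(1, rank - 1)
        center = (r0 + _CELL // 2, c0 + _CELL // 2)
        centers = [center]
        for k in range(5):
            ang = math.radians(18.0 + 72.0 * k)
            centers.append((center[0] + CALC_RING_RADIUS_PX * math.sin(ang),
                            center[1] + CALC_RING_RADIUS_PX * math.cos(ang)))
        for cen in centers:
            mask = _disc_mask(shape, cen, radius)
            calc_map[mask] += da * contrast_scale
            scatter[mask] += ds * scatter_scale
        h = _inscribed_half(radius)
        roi = RoiSpec(center[0] - h, center[1] - h, center[0] + h + 1,
                      center[1] + h + 1)
        layout.append(TestObject("calcification_group", rank, roi,
                                 cell_background((r0, c0))))

    # --- masses: discs, row block 2 ---------------------------------------
    for rank, (radius, da, ds) in enumerate(
            zip(MASS_RADIUS_PX, MASS_CONTRAST, MASS_SCATTER), start=1):
        r0, c0 = cell_origin(2, rank - 1)
        center = (r0 + _CELL // 2, c0 + _CELL // 2)
        mask = _disc_mask(shape, center, radius)
        mass_map[mask] += da * contrast_scale
        scatter[mask] += ds * scatter_scale
        if rank <= 2:  # internal granular structure of the largest masses
            ring = _disc_mask(shape, center, radius // 2 + 2) & ~_disc_mask(
                shape, center, radius // 2 - 1)
            scatter[ring] += 0.5 * ds * scatter_scale
        h = _inscribed_half(radius)
        roi = RoiSpec(center[0] - h, center[1] - h, center[0] + h + 1,
                      center[1] + h + 1)
        layout.append(TestObject("mass", rank, roi, cell_background((r0, c0))))

    attenuation = slab + fiber_map + calc_map + mass_map
    phase = (0.5 * PHASE_RATIO["breast_tissue"] * slab
             + 0.5 * PHASE_RATIO["fiber"] * fiber_map
             + 0.5 * PHASE_RATIO["calcification"] * calc_map
             + 0.5 * PHASE_RATIO["mass"] * mass_map)
    background = RoiSpec(3 * _CELL + 8, 8, 4 * _CELL - 8, 6 * _CELL - 8)

    return PhantomModel(
        attenuation, phase, scatter, pixel_pitch, thickness, layout,
        background_roi=background,
        class_maps={"breast_tissue": slab, "fiber": fiber_map,
                    "calcification": calc_map, "mass": mass_map},
    )


def breast_texture_phantom(shape: tuple[int, int] = (256, 256),
                           glandularity: float = 0.5,
                           lesion_spec: dict | None = None,
                           seed: int = 0,
                           pixel_pitch: float = 0.071,
                           compressed_thickness: float = 4.5,
                           texture_rel_std: float = 0.05,
                           spectral_index: float = 3.0) -> PhantomModel:
    """Breast-like textured phantom with optional inserted lesion.

    The attenuation background is a 1/f^beta random field (power-law
    power spectrum with exponent ``spectral_index``) around the mean
    projected attenuation of a slab of the given glandularity, emulating
    the anatomical clutter of fibroglandular tissue.  ``lesion_spec``
    optionally inserts a spiculated mass (central disc plus a radial
    bundle of thin lines) and/or a cluster of microcalcification specks:

    ``{"center": (row, col), "radius_px": int, "contrast": float,
    "n_spiculae": int, "spicule_length_px": int,
    "calc_specks": int, "calc_radius_px": int, "calc_contrast": float}``

    Scatter is elevated at the specks and along the spiculae.  The same
    seed always reproduces the same phantom bit for bit.
    """
    if not (0.0 <= glandularity <= 1.0):
        raise InvalidInputError("glandularity must lie in [0, 1]")
    if len(shape) != 2 or min(shape) < 16:
        raise InvalidInputError("shape must be 2-D, at least 16x16")

    rng = np.random.default_rng(seed)
    mu = glandularity * MU_GLANDULAR_25KEV + (1 - glandularity) * MU_ADIPOSE_25KEV
    base = mu * compressed_thickness

    fr = np.fft.fftfreq(shape[0])[:, None]
    fc = np.fft.fftfreq(shape[1])[None, :]
    radius = np.hypot(fr, fc)
    radius[0, 0] = np.inf  # no DC power
    amplitude = radius ** (-spectral_index / 2.0)
    noise = np.fft.fft2(rng.standard_normal(shape))
    texture = np.real(np.fft.ifft2(noise * amplitude))
    texture *= (base * texture_rel_std) / texture.std()

    attenuation_bg = np.clip(base + texture, 0.0, None)
    mass_map = np.zeros(shape)
    calc_map = np.zeros(shape)
    scatter = np.zeros(shape)
    layout: list[TestObject] = []

    if lesion_spec is not None:
        spec = dict(lesion_spec)
        center = tuple(spec.get("center", (shape[0] // 2, shape[1] // 2)))
        radius_px = int(spec.get("radius_px", 12))
        contrast = float(spec.get("contrast", 0.08))
        n_spic = int(spec.get("n_spiculae", 8))
        spic_len = int(spec.get("spicule_length_px", 3 * radius_px))

        mass_map[_disc_mask(shape, center, radius_px)] += contrast
        for k in range(n_spic):
            ang = 2.0 * math.pi * k / n_spic + 0.3
            for t in np.arange(radius_px, radius_px + spic_len, 0.5):
                r = int(round(center[0] + t * math.sin(ang)))
                c = int(round(center[1] + t * math.cos(ang)))
                if 0 <= r < shape[0] and 0 <= c < shape[1]:
                    mass_map[r, c] = max(mass_map[r, c], 0.5 * contrast)
                    scatter[r, c] += 0.02
        h = _inscribed_half(radius_px)
        roi = RoiSpec(center[0] - h, center[1] - h, center[0] + h + 1,
                      center[1] + h + 1)
        bg_r = min(center[0] + 2 * radius_px + spic_len // 2, shape[0] - 14)
        bg = RoiSpec(bg_r, 2, bg_r + 12, 14)
        layout.append(TestObject("mass", 1, roi, bg))

        k_specks = int(spec.get("calc_specks", 0))
        if k_specks:
            c_rad = int(spec.get("calc_radius_px", 2))
            c_con = float(spec.get("calc_contrast", 0.15))
            ring = max(4 * c_rad, radius_px + spic_len + 4 * c_rad)
            for k in range(k_specks):
                ang = 2.0 * math.pi * k / k_specks
                cen = (center[0] + ring * math.sin(ang),
                       center[1] + ring * math.cos(ang))
                mask = _disc_mask(shape, cen, c_rad)
                calc_map[mask] += c_con
                scatter[mask] += 0.4
            h = max(1, c_rad)
            cen0 = (int(center[0] + ring * math.sin(0.0)),
                    int(center[1] + ring * math.cos(0.0)))
            roi = RoiSpec(max(cen0[0] - h, 0), max(cen0[1] - h, 0),
                          cen0[0] + h + 1, cen0[1] + h + 1)
            layout.append(TestObject("calcification_group", 1, roi,
                                     RoiSpec(2, 2, 14, 14)))

    attenuation = attenuation_bg + mass_map + calc_map
    phase = (0.5 * PHASE_RATIO["breast_tissue"] * attenuation_bg
             + 0.5 * PHASE_RATIO["mass"] * mass_map
             + 0.5 * PHASE_RATIO["calcification"] * calc_map)
    return PhantomModel(
        attenuation, phase, scatter, pixel_pitch, compressed_thickness,
        layout, background_roi=RoiSpec(2, 2, 30, 30),
        class_maps={"breast_tissue": attenuation_bg, "mass": mass_map,
                    "calcification": calc_map},
    )


def project(phantom: PhantomModel, energy: float
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rescale the stored reference-energy maps to another energy.

    Attenuation contributions are scaled per material class by
    ``mu(E) / mu(E_ref)`` from the shipped attenuation table; phase
    scales with the wavelength ratio ``lambda / lambda_ref = E_ref / E``;
    scatter follows the configured power law ``(E_ref / E) ** p``.
    """
    table = _material_table()
    energies = table["energy_keV"].to_numpy(float)
    if not (energies[0] <= energy <= energies[-1]):
        raise TableRangeError(
            f"energy {energy} keV outside material table "
            f"[{energies[0]}, {energies[-1]}]")

    if phantom.class_maps is None:
        ratio_cols = ["breast_50_50"]
        class_maps = {"breast_50_50": phantom.projected_attenuation}
    else:
        class_maps = phantom.class_maps
        ratio_cols = list(class_maps)
    column_for = {"breast_tissue": "breast_50_50", "fiber": "fiber_nylon",
                  "calcification": "calcification", "mass": "mass_tumor",
                  "breast_50_50": "breast_50_50"}

    e_ref = phantom.reference_energy
    attenuation = np.zeros(phantom.shape)
    for name in ratio_cols:
        col = table[column_for[name]].to_numpy(float)
        mu_e = np.interp(energy, energies, col)
        mu_ref = np.interp(e_ref, energies, col)
        attenuation += class_maps[name] * (mu_e / mu_ref)

    phase = phantom.projected_phase * (e_ref / energy)
    scatter = phantom.projected_scatter * (e_ref / energy) ** phantom.scatter_energy_power
    return attenuation, phase, scatter


def save_phantom(phantom: PhantomModel, directory) -> None:
    """Write a phantom as three float32 TIFFs plus a JSON layout file."""
    import tifffile
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(d / "attenuation.tif",
                     phantom.projected_attenuation.astype(np.float32))
    tifffile.imwrite(d / "phase.tif", phantom.projected_phase.astype(np.float32))
    tifffile.imwrite(d / "scatter.tif", phantom.projected_scatter.astype(np.float32))
    meta = {
        "pixel_pitch_mm": phantom.pixel_pitch,
        "compressed_thickness_cm": phantom.compressed_thickness,
        "reference_energy_keV": phantom.reference_energy,
        "background_roi": (list(phantom.background_roi.__dict__.values())
                           if phantom.background_roi else None),
        "layout": [
            {"category": o.category, "rank": o.rank,
             "roi": [o.roi.row_start, o.roi.col_start, o.roi.row_stop, o.roi.col_stop],
             "background_roi": [o.background_roi.row_start, o.background_roi.col_start,
                                o.background_roi.row_stop, o.background_roi.col_stop]}
            for o in phantom.layout
        ],
    }
    (d / "layout.json").write_text(json.dumps(meta, indent=1))


def load_phantom(directory) -> PhantomModel:
    """Read a phantom directory written by :func:`save_phantom`."""
    import tifffile
    from pathlib import Path

    d = Path(directory)
    meta = json.loads((d / "layout.json").read_text())
    layout = [
        TestObject(o["category"], o["rank"], RoiSpec(*o["roi"]),
                   RoiSpec(*o["background_roi"]))
        for o in meta["layout"]
    ]
    bg = RoiSpec(*meta["background_roi"]) if meta.get("background_roi") else None
    return PhantomModel(
        tifffile.imread(d / "attenuation.tif").astype(float),
        tifffile.imread(d / "phase.tif").astype(float),
        tifffile.imread(d / "scatter.tif").astype(float),
        meta["pixel_pitch_mm"], meta["compressed_thickness_cm"], layout,
        background_roi=bg, reference_energy=meta["reference_energy_keV"],
    )
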