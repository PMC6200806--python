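"""Tile stitching with linear-ramp blending.

A limited beam footprint forces scanning the sample in overlapping
tiles.  Neighbouring tiles are blended across their overlap with linear
ramps: at 0-based overlap position ``i`` of an ``n``-pixel overlap, the
incoming tile weighs ``(i + 1) / (n + 1)`` and the outgoing tile the
complement, so the weights are strictly inside (0, 1) (every acquired
pixel contributes) and sum to one at every position — constant fields
stitch exactly to the same constant.

Differential-phase tiles live on the wrapped (-pi, pi] circle, so they
are blended as complex phasors ``exp(i * dphi)`` and the angle is taken
afterwards, which avoids ramping across the +-pi cut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .retrieval import wrap_phase

__all__ = ["TileLayout", "linear_ramp_weights", "stitch", "stitch_phase",
           "extract_tiles"]


def linear_ramp_weights(overlap: int) -> np.ndarray:
    """Incoming-tile blend weights across an overlap of ``overlap`` px.

    Weight at position ``i`` is ``(i + 1) / (overlap + 1)``; the
    outgoing tile takes ``1 - w``.  ``overlap = 0`` returns an empty
    profile (plain abutment, no blending).
    """
    if overlap < 0:
        raise InvalidInputError("overlap must be >= 0")
    if overlap == 0:
        return np.empty(0)
    return (np.arange(overlap) + 1.0) / (overlap + 1.0)


@dataclass(frozen=True)
class TileLayout:
    """Regular tile grid with fixed overlaps.

    ``grid`` is (rows, cols) of tiles; ``tile_shape`` the per-tile pixel
    shape; ``overlap`` the shared band width in pixels along both axes.
    Offsets are derived: tile (i, j) starts at
    ``(i * (th - overlap), j * (tw - overlap))``.
    """

    grid: tuple[int, int]
    tile_shape: tuple[int, int]
    overlap: int

    def __post_init__(self) -> None:
        if min(self.grid) < 1:
            raise InvalidInputError("grid must have at least one tile per axis")
        if self.overlap < 0:
            raise InvalidInputError("overlap must be >= 0")
        # overlap only constrains axes along which neighbouring tiles exist
        if self.grid[0] > 1 and self.overlap >= self.tile_shape[0]:
            raise InvalidInputError("overlap must be smaller than the tile height")
        if self.grid[1] > 1 and self.overlap >= self.tile_shape[1]:
            raise InvalidInputError("overlap must be smaller than the tile width")

    @property
    def n_tiles(self) -> int:
        return self.grid[0] * self.grid[1]

    @property
    def mosaic_shape(self) -> tuple[int, int]:
        th, tw = self.tile_shape
        return (self.grid[0] * (th - self.overlap) + self.overlap,
                self.grid[1] * (tw - self.overlap) + self.overlap)

    def offset(self, i: int, j: int) -> tuple[int, int]:
        th, tw = self.tile_shape
        return (i * (th - self.overlap), j * (tw - self.overlap))

    def tile_indices(self):
        for i in range(self.grid[0]):
            for j in range(self.grid[1]):
                yield i, j

def _blend_pair(a: np.ndarray, b: np.ndarray, overlap: int,
                axis: int) -> np.ndarray:
    """Join ``b`` onto the trailing edge of ``a`` along ``axis``.

    The overlap is blended in lerp form ``a + w * (b - a)`` with the
    linear ramp ``w``; this is exactly constant-preserving (equal values
    blend to themselves bit for bit).
    """
    a = np.moveaxis(a, axis, -1)
    b = np.moveaxis(b, axis, -1)
    if overlap == 0:
        out = np.concatenate([a, b], axis=-1)
        return np.moveaxis(out, -1, axis)
    w = linear_ramp_weights(overlap)
    blended = a[..., -overlap:] + w * (b[..., :overlap] - a[..., -overlap:])
    out = np.concatenate([a[..., :-overlap], blended, b[..., overlap:]],
                         axis=-1)
    return np.moveaxis(out, -1, axis)


def _accumulate(tiles, layout: TileLayout) -> np.ndarray:
    tiles = [np.asarray(t, dtype=complex if np.iscomplexobj(t) else float)
             for t in tiles]
    if len(tiles) != layout.n_tiles:
        raise InvalidInputError(
            f"expected {layout.n_tiles} tiles, got {len(tiles)}")
    for t in tiles:
        if t.shape != layout.tile_shape:
            raise InvalidInputError("tile shape does not match layout")
    rows, cols = layout.grid
    strips = []
    for i in range(rows):
        strip = tiles[i * cols]
        for j in range(1, cols):
            strip = _blend_pair(strip, tiles[i * cols + j], layout.overlap, 1)
        strips.append(strip)
    mosaic = strips[0]
    for strip in strips[1:]:
        mosaic = _blend_pair(mosaic, strip, layout.overlap, 0)
    return mosaic


def stitch(tiles, layout: TileLayout) -> np.ndarray:
    """Blend tiles into a mosaic with linear-ramp weights.

    Deterministic; overlap weights sum to one at every position, so
    constant tiles stitch exactly to the same constant.
    """
    return np.real(_accumulate(tiles, layout))


def stitch_phase(tiles, layout: TileLayout) -> np.ndarray:
    """Stitch wrapped differential-phase tiles on the phasor circle."""
    phasors = [np.exp(1j * np.asarray(t, dtype=float)) for t in tiles]
    blended = _accumulate(phasors, layout)
    return wrap_phase(np.angle(blended))


def extract_tiles(image: np.ndarray, layout: TileLayout) -> list[np.ndarray]:
    """Cut an image into the overlapping tiles of a layout.

    The inverse of :func:`stitch` for simulation purposes: the image
    must have exactly the layout's mosaic shape.
    """
    image = np.asarray(image)
    if image.shape != layout.mosaic_shape:
        raise InvalidInputError(
            f"image shape {image.shape} != mosaic {layout.mosaic_shape}")
    th, tw = layout.tile_shape
    return [image[r0: r0 + th, c0: c0 + tw]
            for (i, j) in layout.tile_indices()
            for (r0, c0) in [layout.offset(i, j)]]
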