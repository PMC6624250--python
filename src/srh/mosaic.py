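"""Tile mosaics and Fourier-plane grid-artifact removal.

Tiles acquired on a motorized stage abut with zero overlap; stitching is a
pure block placement, exactly invertible by cropping. Because per-tile
intensity offsets leave a periodic seam pattern at the tile pitch, the
stitched RGB image is filtered in the Fourier plane: Gaussian notches are
placed at the grid's spatial-frequency harmonics ``k / tile_px`` cycles/px
(k = 1..harmonics, along both axes and their combinations), the DC bin is
preserved, and an optional per-channel percentile clamp implements the
intensity filtering. Gaussian (rather than hard) notches avoid ringing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Dict, Optional, Tuple

import numpy as np

from ._util import to_uint8
from .errors import CompletenessError, GeometryError, ParameterError
from .stack import ChannelStack


@dataclass
class TileGrid:
    """A complete rectangular grid of homogeneous tiles.

    Tiles may be plain 2-D/3-D arrays, or :class:`ChannelStack` instances
    sharing channel names.
    """

    tiles: Dict[Tuple[int, int], object]
    n_rows: int
    n_cols: int
    tile_px: int
    overlap_px: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1 or self.tile_px < 1:
            raise ParameterError("n_rows, n_cols and tile_px must be positive")
        if self.overlap_px < 0:
            raise ParameterError("overlap_px must be nonnegative")
        missing = [
            (r, c)
            for r in range(self.n_rows)
            for c in range(self.n_cols)
            if (r, c) not in self.tiles
        ]
        if missing:
            raise CompletenessError(f"tile grid is missing tiles at {missing}")
        names = None
        for key, tile in self.tiles.items():
            if isinstance(tile, ChannelStack):
                shape = tile.shape
                if names is None:
                    names = set(tile.names)
                elif set(tile.names) != names:
                    raise GeometryError(f"tile {key} has channel names {tile.names}")
            else:
                shape = np.asarray(tile).shape[:2]
            if shape != (self.tile_px, self.tile_px):
                raise GeometryError(
                    f"tile {key} has shape {shape}, expected {(self.tile_px,) * 2}"
                )


def stitch_tiles(grid: TileGrid):
    """Assemble abutting tiles into one raster (or one ChannelStack).

    Tile (r, c) occupies the half-open block
    ``[r*tile_px, (r+1)*tile_px) x [c*tile_px, (c+1)*tile_px)``.
    """
    if grid.overlap_px != 0:
        raise ParameterError("only abutting tiles (overlap_px == 0) can be stitched")
    t = grid.tile_px
    first = grid.tiles[(0, 0)]
    if isinstance(first, ChannelStack):
        out = {
            name: np.zeros((grid.n_rows * t, grid.n_cols * t)) for name in first.names
        }
        for (r, c), tile in grid.tiles.items():
            for name in first.names:
                out[name][r * t : (r + 1) * t, c * t : (c + 1) * t] = tile[name]
        return ChannelStack(
            channels=out, pixel_size_um=first.pixel_size_um, modality=first.modality
        )
    trailing = np.asarray(first).shape[2:]
    out = np.zeros((grid.n_rows * t, grid.n_cols * t) + trailing, dtype=np.asarray(first).dtype)
    for (r, c), tile in grid.tiles.items():
        out[r * t : (r + 1) * t, c * t : (c + 1) * t] = np.asarray(tile)
    return out


def extract_tile(mosaic: np.ndarray, r: int, c: int, tile_px: int) -> np.ndarray:
    """Crop tile (r, c) back out of a stitched mosaic."""
    return mosaic[r * tile_px : (r + 1) * tile_px, c * tile_px : (c + 1) * tile_px]


def split_into_tiles(stack: ChannelStack, tile_px: int) -> TileGrid:
    """Cut a full-field ChannelStack into an abutting TileGrid."""
    h, w = stack.shape
    if h % tile_px or w % tile_px:
        raise GeometryError(f"stack shape {stack.shape} is not a multiple of tile_px={tile_px}")
    n_rows, n_cols = h // tile_px, w // tile_px
    tiles = {}
    for r in range(n_rows):
        for c in range(n_cols):
            tiles[(r, c)] = stack.copy_with(
                {
                    name: extract_tile(stack[name], r, c, tile_px).copy()
                    for name in stack.names
                }
            )
    return TileGrid(tiles=tiles, n_rows=n_rows, n_cols=n_cols, tile_px=tile_px)


@dataclass(frozen=True)
class GridFilterParams:
    """Fixed-mask notch filter for the tile-boundary grid.

    ``harmonics=None`` (the default) notches every grid harmonic up to the
    Nyquist frequency of the tile pitch — the seam lines are only two pixels
    wide, so their comb spectrum extends to high orders.
    """

    notch_radius_bins: float = 1.5
    harmonics: Optional[int] = None
    notch_depth: float = 1.0
    intensity_clip: Optional[Tuple[float, float]] = None  # percentiles [low, high]

    def __post_init__(self) -> None:
        if self.notch_radius_bins <= 0:
            raise ParameterError("notch_radius_bins must be positive")
        if self.harmonics is not None and self.harmonics < 1:
            raise ParameterError("harmonics must be >= 1")
        if not 0.0 <= self.notch_depth <= 1.0:
            raise ParameterError("notch_depth must be in [0, 1]")
        if self.intensity_clip is not None:
            lo, hi = self.intensity_clip
            if not 0 <= lo < hi <= 100:
                raise ParameterError("intensity_clip percentiles must satisfy 0 <= low < high <= 100")


def grid_notch_mask(
    shape: Tuple[int, int],
    tile_px: int,
    params: GridFilterParams,
    notch_rows: bool = True,
    notch_cols: bool = True,
) -> np.ndarray:
    """Multiplicative Fourier mask with Gaussian notches at grid harmonics.

    Frequencies are expressed in FFT bins of the full mosaic; the grid
    harmonic ``k / tile_px`` cycles/px falls on bin ``k * (size / tile_px)``.
    Seam lines concentrate their energy on the frequency axes, so notches
    are placed along each axis for k = 1..harmonics plus the low-order
    diagonal combinations (seam crossings). ``notch_rows``/``notch_cols``
    disable the harmonics of an axis that has no seams (a single tile along
    it).
    """
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None] * h  # signed bin coordinates
    fx = np.fft.fftfreq(w)[None, :] * w
    mask = np.ones(shape, dtype=np.float64)
    two_r2 = 2.0 * params.notch_radius_bins**2
    n_harm = params.harmonics if params.harmonics is not None else max(tile_px // 2, 1)
    n_cross = min(n_harm, 2)
    centers = []
    if notch_rows:
        centers += [(j, 0) for j in range(1, n_harm + 1)]
    if notch_cols:
        centers += [(0, k) for k in range(1, n_harm + 1)]
    if notch_rows and notch_cols:
        centers += [
            (j, k) for j, k in product(range(1, n_cross + 1), repeat=2)
        ]
    for j, k in centers:
        cy = j * h / tile_px
        cx = k * w / tile_px
        if np.hypot(cy, cx) <= params.notch_radius_bins:
            raise ParameterError(
                f"notch at grid harmonic ({j}, {k}) lies within one radius of the "
                "DC bin; reduce notch_radius_bins or use more tiles"
            )
        for sy in {1.0, -1.0} if j else {1.0}:
            for sx in {1.0, -1.0} if k else {1.0}:
                d2 = (fy - sy * cy) ** 2 + (fx - sx * cx) ** 2
                mask *= 1.0 - params.notch_depth * np.exp(-d2 / two_r2)
    mask[0, 0] = 1.0  # DC preserved exactly: channel means untouched
    return mask


def remove_grid_artifact(
    mosaic_rgb: np.ndarray,
    grid_geom: Tuple[int, int, int],
    params: GridFilterParams,
) -> np.ndarray:
    """Notch-filter the stitching grid out of an RGB mosaic.

    Each of R, G, B is transformed, multiplied by the fixed notch mask,
    inverse-transformed, optionally percentile-clamped, and re-quantized to
    8 bits.
    """
    n_rows, n_cols, tile_px = grid_geom
    rgb = np.asarray(mosaic_rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise GeometryError(f"expected an (H, W, 3) RGB raster, got {rgb.shape}")
    if rgb.shape[0] != n_rows * tile_px or rgb.shape[1] != n_cols * tile_px:
        raise GeometryError(
            f"mosaic shape {rgb.shape[:2]} inconsistent with grid "
            f"{n_rows}x{n_cols} tiles of {tile_px} px"
        )
    mask = grid_notch_mask(
        rgb.shape[:2], tile_px, params, notch_rows=n_rows > 1, notch_cols=n_cols > 1
    )
    out = np.empty_like(rgb, dtype=np.float64)
    for ch in range(3):
        spec = np.fft.fft2(rgb[..., ch].astype(np.float64))
        filtered = np.fft.ifft2(spec * mask).real
        if params.intensity_clip is not None:
            lo, hi = np.percentile(filtered, params.intensity_clip)
            filtered = np.clip(filtered, lo, hi)
        out[..., ch] = filtered
    return to_uint8(out)
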