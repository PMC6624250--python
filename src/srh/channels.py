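"""Derived-channel arithmetic and grey-level preparation.

Three steps sit between acquisition and coloring:

* nuclei subtraction: ``SRS_nuclei = SRS2930 - SRS2845`` (clipped at zero;
  the nuclei signal is physically nonnegative),
* quantization of the floating-point rasters onto the [0, 255] grey scale
  the lookup tables are defined on,
* threshold computation ``Threshold = k * Mean`` with ``k`` adjustable from
  0 to 2 in steps of 0.01, where Mean is the arithmetic mean of the grey
  image feeding the compositor (global over the stitched image by default).

Subtraction is done on calibrated raw values *before* quantization to avoid
8-bit rounding bias in the difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from ._util import to_uint8
from .errors import GeometryError, ParameterError

QUANTIZE_MODES = ("minmax", "percentile")


@dataclass
class GreyImage:
    """An 8-bit single-channel raster with a physical pixel size."""

    pixels: np.ndarray
    name: str = ""
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.size == 0:
            raise GeometryError(f"GreyImage needs a non-empty 2-D raster, got shape {arr.shape}")
        if self.pixel_size_um <= 0:
            raise GeometryError("pixel_size_um must be positive")
        if arr.dtype != np.uint8:
            if np.any((arr < 0) | (arr > 255)) or not np.issubdtype(arr.dtype, np.integer):
                raise GeometryError("GreyImage values must be integers in [0, 255]")
            arr = arr.astype(np.uint8)
        self.pixels = arr

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    def mean(self) -> float:
        return float(self.pixels.mean())


@dataclass(frozen=True)
class ThresholdSet:
    """The three k coefficients and their derived ``k * Mean`` thresholds."""

    k_collagen: float
    k_nuclei: float
    k_cellbody: float
    threshold_collagen: float
    threshold_nuclei: float
    threshold_cellbody: float
    #: means of the source images, kept for provenance checking
    source_means: Optional[Tuple[float, float, float]] = None


def subtract_nuclei(srs2930: np.ndarray, srs2845: np.ndarray) -> np.ndarray:
    """Element-wise ``SRS2930 - SRS2845`` with negatives clipped to zero."""
    a = np.asarray(srs2930, dtype=np.float64)
    b = np.asarray(srs2845, dtype=np.float64)
    if a.shape != b.shape:
        raise GeometryError(f"shape mismatch: {a.shape} vs {b.shape}")
    return np.clip(a - b, 0.0, None)


def quantize_grey(
    raster: np.ndarray,
    mode: str = "minmax",
    p_low: float = 1.0,
    p_high: float = 99.0,
    name: str = "",
    pixel_size_um: float = 1.0,
) -> GreyImage:
    """Affine-map a nonnegative raster onto the [0, 255] grey scale.

    ``minmax`` stretches the full data range; ``percentile`` stretches the
    [p_low, p_high] percentile window (robust against hot pixels), clipping
    outside it. A constant raster maps to all zeros.
    """
    arr = np.asarray(raster, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise GeometryError(f"quantize_grey needs a non-empty 2-D raster, got shape {arr.shape}")
    if mode not in QUANTIZE_MODES:
        raise ParameterError(f"unknown quantization mode {mode!r}")
    if mode == "percentile":
        if not p_low < p_high:
            raise ParameterError("p_low must be < p_high")
        lo, hi = np.percentile(arr, [p_low, p_high])
    else:
        lo, hi = float(arr.min()), float(arr.max())
    if hi <= lo:
        pixels = np.zeros(arr.shape, dtype=np.uint8)
    else:
        pixels = to_uint8((arr - lo) / (hi - lo) * 255.0)
    return GreyImage(pixels=pixels, name=name, pixel_size_um=pixel_size_um)


def _round_k(k: float) -> float:
    """Snap a slider coefficient to its 0.01 granularity."""
    if not 0.0 <= k <= 2.0:
        raise ParameterError(f"threshold coefficient k={k} outside [0, 2]")
    return round(k * 100.0) / 100.0


def compute_thresholds(
    shg: GreyImage,
    nuclei: GreyImage,
    cellbody: GreyImage,
    k_collagen: float,
    k_nuclei: float,
    k_cellbody: float,
) -> ThresholdSet:
    """Derive ``Threshold = k * Mean`` for the three composited layers."""
    ks = (_round_k(k_collagen), _round_k(k_nuclei), _round_k(k_cellbody))
    means = (shg.mean(), nuclei.mean(), cellbody.mean())
    return ThresholdSet(
        k_collagen=ks[0],
        k_nuclei=ks[1],
        k_cellbody=ks[2],
        threshold_collagen=ks[0] * means[0],
        threshold_nuclei=ks[1] * means[1],
        threshold_cellbody=ks[2] * means[2],
        source_means=means,
    )
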