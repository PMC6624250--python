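"""Virtual-stain lookup tables.

Each LUT maps the 256 grey levels of a prepared channel onto RGB so that the
rendered image mimics one of the three HES stains: eosin (pink, cell
bodies), hematoxylin (dark purple, nuclei), saffron (orange, collagen).
Tables ramp from pure white at grey 0 through a midtone to a dark anchor at
grey 255, piecewise-linearly per channel, so stronger signal always renders
as a darker stain (luminance is non-increasing in grey level). Four shade
variants per family differ in midtone saturation.

The exact hues of a stain are cosmetic and instrument-specific; anchors here
are sensible defaults and can be overridden, or whole 256x3 palettes pinned
via CSV (:func:`save_lut_csv` / :func:`load_lut_csv`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from ._util import to_uint8
from .errors import ParameterError, RegistryError

EOSIN = "eosin"
HEMATOXYLIN = "hematoxylin"
SAFFRON = "saffron"
FAMILIES = (EOSIN, HEMATOXYLIN, SAFFRON)

WHITE = (255, 255, 255)

#: darkest anchor color of each stain family (grey level 255)
DARK_ANCHORS = {
    EOSIN: (222, 64, 134),  # pink
    HEMATOXYLIN: (70, 35, 90),  # dark purple, B > R > G
    SAFFRON: (235, 140, 30),  # orange
}

#: midtone saturation of each shade variant (fraction of the dark anchor
#: mixed into white at grey level 128)
VARIANT_SATURATIONS = (0.35, 0.45, 0.55, 0.65)

_MIDTONE_GREY = 128
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class LUT:
    """A 256-entry grey -> RGB table for one stain shade."""

    family: str
    variant: int
    table: np.ndarray  # (256, 3) uint8

    def __post_init__(self) -> None:
        t = np.asarray(self.table)
        if t.shape != (256, 3):
            raise ParameterError(f"LUT table must be 256x3, got {t.shape}")
        object.__setattr__(self, "table", t.astype(np.uint8))
        self.check()

    def check(self) -> None:
        """Raise if any LUT invariant is violated."""
        t = self.table.astype(np.float64)
        if tuple(self.table[0]) != WHITE:
            raise ParameterError("LUT entry 0 must be pure white")
        lum = t @ _LUMA
        if np.any(np.diff(lum) > 1e-9):
            raise ParameterError("LUT luminance must be non-increasing in grey level")

    def luminance(self) -> np.ndarray:
        return self.table.astype(np.float64) @ _LUMA


def n_variants(family: str) -> int:
    if family not in FAMILIES:
        raise RegistryError(f"unknown LUT family {family!r}; expected one of {FAMILIES}")
    return len(VARIANT_SATURATIONS)


def ramp_table(
    anchor_greys: Sequence[int], anchor_colors: Sequence[Tuple[float, float, float]]
) -> np.ndarray:
    """Piecewise-linear RGB ramp through (grey, color) anchors, as uint8.

    Anchor grey levels must be strictly increasing and span 0..255.
    """
    greys = np.asarray(anchor_greys, dtype=np.float64)
    colors = np.asarray(anchor_colors, dtype=np.float64)
    if greys[0] != 0 or greys[-1] != 255 or np.any(np.diff(greys) <= 0):
        raise ParameterError("anchor greys must increase strictly from 0 to 255")
    if colors.shape != (len(greys), 3):
        raise ParameterError("need one RGB triple per anchor")
    g = np.arange(256, dtype=np.float64)
    table = np.stack([np.interp(g, greys, colors[:, c]) for c in range(3)], axis=1)
    return to_uint8(table)


def build_lut(
    family: str,
    variant: int = 0,
    dark_anchor: Tuple[float, float, float] | None = None,
) -> LUT:
    """Construct one stain-shade LUT.

    The midtone at grey 128 is ``white + s * (dark - white)`` with the
    variant's saturation ``s``; both ramp segments are therefore monotone
    per RGB channel, which guarantees non-increasing luminance.
    """
    if family not in FAMILIES:
        raise RegistryError(f"unknown LUT family {family!r}; expected one of {FAMILIES}")
    if not 0 <= variant < len(VARIANT_SATURATIONS):
        raise RegistryError(
            f"family {family!r} has variants 0..{len(VARIANT_SATURATIONS) - 1}, got {variant}"
        )
    dark = np.asarray(dark_anchor if dark_anchor is not None else DARK_ANCHORS[family], dtype=np.float64)
    if np.any(dark < 0) or np.any(dark > 255):
        raise ParameterError("dark anchor components must be in [0, 255]")
    white = np.asarray(WHITE, dtype=np.float64)
    s = VARIANT_SATURATIONS[variant]
    mid = white + s * (dark - white)
    table = ramp_table([0, _MIDTONE_GREY, 255], [tuple(white), tuple(mid), tuple(dark)])
    table[0] = WHITE  # exact white background anchor
    return LUT(family=family, variant=variant, table=table)


def apply_lut(image, lut: LUT) -> np.ndarray:
    """Color a grey image through the table: ``out[i, j] = table[grey[i, j]]``."""
    pixels = image.pixels if hasattr(image, "pixels") else np.asarray(image)
    if pixels.dtype != np.uint8:
        if np.any((pixels < 0) | (pixels > 255)):
            raise ParameterError("grey values must be in [0, 255]")
        pixels = pixels.astype(np.uint8)
    return lut.table[pixels]


def save_lut_csv(lut: LUT, path) -> None:
    np.savetxt(path, lut.table, fmt="%d", delimiter=",", header="R,G,B", comments="")


def load_lut_csv(path, family: str = EOSIN, variant: int = 0) -> LUT:
    """Load a pinned 256x3 palette; full LUT invariants are enforced."""
    table = np.loadtxt(path, delimiter=",", skiprows=1)
    if table.shape != (256, 3):
        raise ParameterError(f"LUT CSV must contain 256 rows x 3 columns, got {table.shape}")
    if np.any(table < 0) or np.any(table > 255):
        raise ParameterError("LUT CSV components must be in [0, 255]")
    return LUT(family=family, variant=variant, table=table.astype(np.uint8))
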