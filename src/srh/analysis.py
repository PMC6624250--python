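"""Quantitative readouts of rendered SRH images.

Utilities to classify each rendered pixel by the stain family its color is
closest to, and to count nuclei as connected components of
hematoxylin-classified pixels. Used to close the loop between the phantom's
ground truth and the final rendering.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np
from scipy import ndimage

from .lut import LUT, _LUMA

BACKGROUND = 0

#: pixels at or above this luminance are treated as unstained background
WHITE_LUMINANCE = 240.0


def classify_stain(
    rgb: np.ndarray,
    luts: Dict[str, LUT],
    white_luminance: float = WHITE_LUMINANCE,
) -> Dict[str, np.ndarray]:
    """Assign each pixel to the nearest stain family's color ramp.

    For every family the distance of a pixel to the closest table entry is
    computed (near-white table entries are ignored as ramp representatives,
    since every ramp starts at white); pixels brighter than
    ``white_luminance`` are background. Returns a boolean mask per family.
    """
    arr = np.asarray(rgb)
    h, w, _ = arr.shape
    flat = arr.reshape(-1, 3)
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    uniq_f = uniq.astype(np.float64)
    lum = uniq_f @ _LUMA
    foreground = lum < white_luminance

    names = list(luts)
    dists = np.full((len(names), len(uniq)), np.inf)
    for i, name in enumerate(names):
        table = luts[name].table.astype(np.float64)
        ramp = table[(table @ _LUMA) < white_luminance]
        if len(ramp) == 0:
            continue
        d = np.linalg.norm(uniq_f[:, None, :] - ramp[None, :, :], axis=2)
        dists[i] = d.min(axis=1)
    nearest = np.argmin(dists, axis=0)

    masks = {}
    for i, name in enumerate(names):
        m = foreground & (nearest == i)
        masks[name] = m[inverse].reshape(h, w)
    return masks


def count_stained_objects(
    mask: np.ndarray, min_area_px: int = 1
) -> int:
    """Count connected components (8-connectivity) of at least `min_area_px`."""
    labeled, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return 0
    sizes = np.bincount(labeled.ravel())[1:]
    return int(np.count_nonzero(sizes >= min_area_px))


def count_nuclei(
    rgb: np.ndarray,
    hematoxylin: LUT,
    other_luts: Optional[Dict[str, LUT]] = None,
    min_area_px: int = 4,
    white_luminance: float = WHITE_LUMINANCE,
) -> int:
    """Count nuclei in a rendered SRH image.

    Pixels are classified against the hematoxylin ramp versus the other
    stain ramps; hematoxylin components of at least `min_area_px` pixels
    count as one nucleus each.
    """
    luts = {"hematoxylin": hematoxylin}
    if other_luts:
        luts.update(other_luts)
    masks = classify_stain(rgb, luts, white_luminance=white_luminance)
    return count_stained_objects(masks["hematoxylin"], min_area_px=min_area_px)
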