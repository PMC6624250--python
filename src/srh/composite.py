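"""Priority compositing of the colored layers into a virtual-HES image.

Collagen fibres show up in both the nuclei contrast and SHG, so SHG gets
priority; the layers stack (top to bottom) SHG, nuclei, cell body, and a
pixel not claimed by any layer is left white. Per pixel, strictly in order:

    if   SHG    > ThresholdCollagen: take the saffron-colored SHG pixel
    elif nuclei > ThresholdNuclei:   take the hematoxylin-colored pixel
    elif cell   > ThresholdCellbody: take the eosin-colored pixel
    else:                            white (255, 255, 255)

Comparisons are strict, so a value equal to its threshold falls through to
the next branch. There is no blending: the routine is hard selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List

import numpy as np

from .channels import GreyImage, ThresholdSet
from .errors import GeometryError, ProvenanceWarning

WHITE_RGB = (255, 255, 255)


@dataclass
class SRHImage:
    """Final or intermediate RGB histology rendering with provenance."""

    rgb: np.ndarray  # (H, W, 3) uint8
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.rgb)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise GeometryError(f"SRHImage needs an (H, W, 3) raster, got {arr.shape}")
        if arr.dtype != np.uint8:
            if np.any((arr < 0) | (arr > 255)):
                raise GeometryError("RGB components must be in [0, 255]")
            arr = arr.astype(np.uint8)
        self.rgb = arr
        self.provenance.setdefault("steps", [])

    def with_step(self, name: str, rgb: np.ndarray, **params) -> "SRHImage":
        """New image with one more processing step appended to provenance."""
        prov = {k: v for k, v in self.provenance.items()}
        prov["steps"] = list(self.provenance["steps"]) + [{"step": name, **params}]
        return SRHImage(rgb=rgb, provenance=prov)

    @property
    def steps(self) -> List[dict]:
        return self.provenance["steps"]


def composite_srh(
    shg: GreyImage,
    nuclei: GreyImage,
    cellbody: GreyImage,
    shg_colored: np.ndarray,
    nuclei_colored: np.ndarray,
    cellbody_colored: np.ndarray,
    thresholds: ThresholdSet,
) -> SRHImage:
    """Build the preliminary SRH image by per-pixel priority selection."""
    shape = shg.shape
    greys = (shg, nuclei, cellbody)
    colors = (shg_colored, nuclei_colored, cellbody_colored)
    for g in greys[1:]:
        if g.shape != shape:
            raise GeometryError(f"grey image shape {g.shape} != {shape}")
    for c in colors:
        c = np.asarray(c)
        if c.shape != shape + (3,):
            raise GeometryError(f"colored raster shape {c.shape} != {shape + (3,)}")

    if thresholds.source_means is not None:
        ks = (thresholds.k_collagen, thresholds.k_nuclei, thresholds.k_cellbody)
        ts = (
            thresholds.threshold_collagen,
            thresholds.threshold_nuclei,
            thresholds.threshold_cellbody,
        )
        for g, k, t in zip(greys, ks, ts):
            if abs(k * g.mean() - t) > 1e-6:
                warnings.warn(
                    f"threshold {t} does not equal k*mean of image {g.name!r}; "
                    "thresholds may derive from different images",
                    ProvenanceWarning,
                    stacklevel=2,
                )
                break

    out = np.empty(shape + (3,), dtype=np.uint8)
    out[...] = WHITE_RGB
    # paint lowest priority first, let higher layers overwrite
    m_cell = cellbody.pixels > thresholds.threshold_cellbody
    out[m_cell] = np.asarray(cellbody_colored, dtype=np.uint8)[m_cell]
    m_nuc = nuclei.pixels > thresholds.threshold_nuclei
    out[m_nuc] = np.asarray(nuclei_colored, dtype=np.uint8)[m_nuc]
    m_shg = shg.pixels > thresholds.threshold_collagen
    out[m_shg] = np.asarray(shg_colored, dtype=np.uint8)[m_shg]

    provenance = {
        "steps": [
            {
                "step": "composite",
                "order": ["SHG", "nuclei", "cellbody", "white"],
                "k": [thresholds.k_collagen, thresholds.k_nuclei, thresholds.k_cellbody],
                "thresholds": [
                    thresholds.threshold_collagen,
                    thresholds.threshold_nuclei,
                    thresholds.threshold_cellbody,
                ],
            }
        ]
    }
    return SRHImage(rgb=out, provenance=provenance)
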