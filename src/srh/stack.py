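"""Co-registered multichannel rasters.

A :class:`ChannelStack` holds the named grey-level channels of one tile or one
stitched mosaic, all sharing a shape and a physical pixel size. Channel names
follow the microscope semantics: ``SRS2845`` (CH2, cell bodies), ``SRS2930``
(CH3, cell bodies + nuclei), ``FMSRS`` (demodulated SRS2930 - SRS2845),
``SHG`` (fibrillar collagen), ``TPEF``/``CARS`` (auxiliary cell-body
contrast).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .errors import GeometryError

SRS2845 = "SRS2845"
SRS2930 = "SRS2930"
FMSRS = "FMSRS"
SHG = "SHG"
TPEF = "TPEF"
CARS = "CARS"

#: Channel names understood by the pipeline and the tile readers/writers.
KNOWN_CHANNELS = (SRS2845, SRS2930, FMSRS, SHG, TPEF, CARS)


@dataclass
class ChannelStack:
    """A set of co-registered single-channel rasters plus modality metadata."""

    channels: Dict[str, np.ndarray]
    pixel_size_um: float
    modality: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise GeometryError("a ChannelStack needs at least one channel")
        if self.pixel_size_um <= 0:
            raise GeometryError("pixel_size_um must be positive")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise GeometryError(f"channels have inconsistent shapes: {sorted(shapes)}")
        (shape,) = shapes
        if len(shape) != 2:
            raise GeometryError(f"channels must be 2-D rasters, got shape {shape}")
        self.channels = {
            name: np.asarray(a, dtype=np.float64) for name, a in self.channels.items()
        }

    @property
    def shape(self) -> tuple:
        return next(iter(self.channels.values())).shape

    @property
    def names(self) -> tuple:
        return tuple(self.channels)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def copy_with(self, channels: Dict[str, np.ndarray], modality: Optional[str] = None) -> "ChannelStack":
        return ChannelStack(
            channels=channels,
            pixel_size_um=self.pixel_size_um,
            modality=self.modality if modality is None else modality,
            meta=dict(self.meta),
        )
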