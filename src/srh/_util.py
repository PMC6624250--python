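"""Shared numeric helpers.

All integer rounding in the pipeline is half-up (0.5 -> 1), applied through
:func:`round_half_up` so every stage agrees on tie handling.
"""

from __future__ import annotations

import numpy as np


def round_half_up(x) -> np.ndarray:
    """Round to nearest integer with ties going up (as floats)."""
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


def to_uint8(x) -> np.ndarray:
    """Round half-up, clip to [0, 255] and cast to uint8."""
    return np.clip(round_half_up(x), 0, 255).astype(np.uint8)


def derive_seed(seed_sequence: np.random.SeedSequence) -> int:
    """Collapse a SeedSequence into a small positive integer seed (< 2**31)."""
    return int(seed_sequence.generate_state(1, dtype=np.uint32)[0] % (2**31))
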