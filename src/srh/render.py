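"""Final rendering and the end-to-end pipeline driver.

Rendering finishes a composited mosaic with the two cosmetic steps of the
processing protocol: a 3x3 box smoothing (each pixel replaced by 1/9 of its
neighborhood sum) and, when asked for, per-R,G,B 256-bin histogram
equalization. Equalization is off by default; when on, fully white
background pixels are excluded from histogram building by default so that
large empty areas do not wash out the stain contrast.

:func:`run_pipeline` chains every stage: phantom (or tile input) ->
acquisition -> calibration -> stitching -> nuclei derivation ->
quantization -> LUT coloring -> k*Mean thresholds -> priority compositing
-> Fourier grid removal -> smoothing -> equalization, recording every step
and seed in the image provenance.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, replace
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage

from ._util import derive_seed, round_half_up, to_uint8
from .acquisition import FM_SRS, LAMBDA_SWITCH, acquire, calibrate_power
from .channels import GreyImage, compute_thresholds, quantize_grey, subtract_nuclei
from .composite import SRHImage, composite_srh
from .errors import GeometryError, ParameterError
from .lut import apply_lut
from .mosaic import TileGrid, remove_grid_artifact, split_into_tiles, stitch_tiles
from .phantom import generate_phantom, rasterize_channels
from .stack import FMSRS, SHG, SRS2845, SRS2930

log = logging.getLogger(__name__)

PAD_MODES = {"replicate": "nearest", "reflect": "reflect"}


@dataclass(frozen=True)
class RenderParams:
    smooth: bool = True
    equalize: bool = False
    pad_mode: str = "replicate"
    equalize_exclude_white: bool = True

    def __post_init__(self) -> None:
        if self.pad_mode not in PAD_MODES:
            raise ParameterError(f"pad_mode must be one of {tuple(PAD_MODES)}")


def smooth_3x3(rgb: np.ndarray, pad_mode: str = "replicate") -> np.ndarray:
    """Average each pixel with its 3x3 neighborhood, per RGB channel."""
    if pad_mode not in PAD_MODES:
        raise ParameterError(f"pad_mode must be one of {tuple(PAD_MODES)}")
    arr = np.asarray(rgb, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[..., None]
        squeeze = True
    else:
        squeeze = False
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise GeometryError(f"raster {arr.shape[:2]} is smaller than the 3x3 kernel")
    out = np.empty_like(arr)
    for ch in range(arr.shape[2]):
        out[..., ch] = ndimage.uniform_filter(arr[..., ch], size=3, mode=PAD_MODES[pad_mode])
    out = to_uint8(out)
    return out[..., 0] if squeeze else out


def _equalize_channel(values: np.ndarray, sample: np.ndarray) -> np.ndarray:
    """256-bin histogram equalization mapping built from `sample` pixels."""
    hist = np.bincount(sample.ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    if total == 0:
        return values
    cdf = np.cumsum(hist) / total
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    if cdf_min >= 1.0:  # single occupied level: degenerate cdf maps to 0
        mapping = np.zeros(256, dtype=np.uint8)
    else:
        mapping = to_uint8(255.0 * (cdf - cdf_min) / (1.0 - cdf_min))
    return mapping[values]


def equalize_histogram(rgb: np.ndarray, exclude_white: bool = True) -> np.ndarray:
    """Per-channel histogram equalization of an 8-bit RGB raster.

    With ``exclude_white``, pixels that are (255, 255, 255) in all three
    channels are left untouched and do not contribute to the histograms.
    """
    arr = np.asarray(rgb)
    if arr.ndim != 3 or arr.shape[2] != 3 or arr.dtype != np.uint8:
        raise GeometryError("equalize_histogram expects an (H, W, 3) uint8 raster")
    out = arr.copy()
    if exclude_white:
        stained = ~np.all(arr == 255, axis=2)
        if not stained.any():
            return out
        for ch in range(3):
            channel = arr[..., ch]
            mapped = _equalize_channel(channel, channel[stained])
            out[..., ch] = np.where(stained, mapped, channel)
    else:
        for ch in range(3):
            out[..., ch] = _equalize_channel(arr[..., ch], arr[..., ch])
    return out


# ---------------------------------------------------------------------------
# pipeline driver

def _composite_global(g_shg, g_nuc, g_cell, c_shg, c_nuc, c_cell, config) -> SRHImage:
    thr = compute_thresholds(
        g_shg, g_nuc, g_cell, config.k_collagen, config.k_nuclei, config.k_cellbody
    )
    return composite_srh(g_shg, g_nuc, g_cell, c_shg, c_nuc, c_cell, thr)


def _composite_per_tile(g_shg, g_nuc, g_cell, c_shg, c_nuc, c_cell, config, n_rows, n_cols, tile_px) -> SRHImage:
    """Per-tile k*Mean thresholds: composite each tile block independently."""
    h, w = g_shg.shape
    rgb = np.empty((h, w, 3), dtype=np.uint8)
    ks = []
    for r in range(n_rows):
        for c in range(n_cols):
            sl = (slice(r * tile_px, (r + 1) * tile_px), slice(c * tile_px, (c + 1) * tile_px))
            sub = lambda g: GreyImage(g.pixels[sl], name=g.name, pixel_size_um=g.pixel_size_um)
            tile_img = _composite_global(
                sub(g_shg), sub(g_nuc), sub(g_cell),
                c_shg[sl], c_nuc[sl], c_cell[sl], config,
            )
            rgb[sl] = tile_img.rgb
            ks.append(tile_img.steps[0]["thresholds"])
    return SRHImage(
        rgb=rgb,
        provenance={"steps": [{"step": "composite", "per_tile_mean": True, "thresholds": ks}]},
    )


def run_pipeline(config, seed: Optional[int] = None, save_intermediates: bool = False):
    """Execute the full SRH pipeline described by a :class:`PipelineConfig`.

    Returns the final :class:`SRHImage`; with ``save_intermediates`` a
    ``(image, intermediates)`` tuple where the dict holds every stage's
    output keyed by stage name.
    """
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    phantom_ss, acq_ss = ss.spawn(2)
    inter: Dict[str, object] = {}
    steps = []
    t_start = time.perf_counter()

    def _mark(name, **params):
        steps.append({"step": name, **params})
        log.info("stage %-16s done at %.2fs", name, time.perf_counter() - t_start)

    acq = config.acquisition
    modality = acq.modality

    if config.tile_dir is not None:
        from .io_formats import read_tile_directory

        grid = read_tile_directory(config.tile_dir)
        _mark("load_tiles", tile_dir=str(config.tile_dir))
    else:
        ph = config.phantom
        if not config.phantom_seed_explicit:
            ph = replace(ph, seed=derive_seed(phantom_ss))
        truth = generate_phantom(ph)
        _mark("phantom", grade=ph.grade, seed=ph.seed, n_glands=len(truth.gland_outlines))
        clean = rasterize_channels(truth, config.blur_sigma_um)
        _mark("rasterize", blur_sigma_um=config.blur_sigma_um)
        full = split_into_tiles(clean, acq.tile_px)
        children = acq_ss.spawn(full.n_rows * full.n_cols)
        tiles = {}
        for idx, key in enumerate(sorted(full.tiles)):
            p = replace(acq, seed=derive_seed(children[idx]))
            tiles[key] = acquire(full.tiles[key], p)
        grid = TileGrid(tiles=tiles, n_rows=full.n_rows, n_cols=full.n_cols, tile_px=acq.tile_px)
        _mark("acquire", modality=modality, accumulations=acq.accumulations,
              noise_sigma=acq.noise_sigma, tiles=[full.n_rows, full.n_cols])
        if save_intermediates:
            inter["truth"] = truth
            inter["clean"] = clean

    mos = stitch_tiles(grid)
    _mark("stitch", n_rows=grid.n_rows, n_cols=grid.n_cols, tile_px=grid.tile_px)

    if config.calibration is not None:
        mos = mos.copy_with(
            {name: calibrate_power(mos[name], config.calibration) for name in mos.names}
        )
        _mark("calibrate",
              reference_signal=config.calibration.reference_signal,
              reference_nominal=config.calibration.reference_nominal)
    if save_intermediates:
        inter["mosaic"] = mos

    if modality == LAMBDA_SWITCH:
        nuclei_raw = subtract_nuclei(mos[SRS2930], mos[SRS2845])
        cell_raw, cell_name = mos[SRS2845], SRS2845
        _mark("derive_nuclei", method="subtraction")
    else:
        nuclei_raw = np.clip(mos[FMSRS], 0.0, None)
        cell_name = config.cellbody_source
        if cell_name not in mos:
            raise GeometryError(f"cellbody_source {cell_name!r} not present in the acquired stack")
        cell_raw = mos[cell_name]
        _mark("derive_nuclei", method="fm_demodulated")

    def q(arr, name):
        return quantize_grey(arr, config.quant_mode, config.p_low, config.p_high,
                             name=name, pixel_size_um=mos.pixel_size_um)

    g_shg, g_nuc, g_cell = q(mos[SHG], SHG), q(nuclei_raw, "nuclei"), q(cell_raw, cell_name)
    _mark("quantize", mode=config.quant_mode)

    c_shg = apply_lut(g_shg, config.lut_shg)
    c_nuc = apply_lut(g_nuc, config.lut_nuclei)
    c_cell = apply_lut(g_cell, config.lut_cellbody)
    _mark("colorize", luts={
        "shg": [config.lut_shg.family, config.lut_shg.variant],
        "nuclei": [config.lut_nuclei.family, config.lut_nuclei.variant],
        "cellbody": [config.lut_cellbody.family, config.lut_cellbody.variant],
    })
    if save_intermediates:
        inter["grey"] = {"shg": g_shg, "nuclei": g_nuc, "cellbody": g_cell}
        inter["colored"] = {"shg": c_shg, "nuclei": c_nuc, "cellbody": c_cell}

    if config.per_tile_mean:
        srh = _composite_per_tile(g_shg, g_nuc, g_cell, c_shg, c_nuc, c_cell,
                                  config, grid.n_rows, grid.n_cols, grid.tile_px)
    else:
        srh = _composite_global(g_shg, g_nuc, g_cell, c_shg, c_nuc, c_cell, config)
    steps.extend(srh.steps)
    log.info("stage %-16s done at %.2fs", "composite", time.perf_counter() - t_start)
    rgb = srh.rgb
    if save_intermediates:
        inter["preliminary"] = rgb.copy()

    if config.grid_filter_enabled and (grid.n_rows > 1 or grid.n_cols > 1):
        rgb = remove_grid_artifact(rgb, (grid.n_rows, grid.n_cols, grid.tile_px),
                                   config.grid_filter)
        _mark("grid_filter",
              notch_radius_bins=config.grid_filter.notch_radius_bins,
              harmonics=config.grid_filter.harmonics,
              notch_depth=config.grid_filter.notch_depth,
              intensity_clip=list(config.grid_filter.intensity_clip)
              if config.grid_filter.intensity_clip else None)
        if save_intermediates:
            inter["grid_filtered"] = rgb.copy()

    if config.render.smooth:
        rgb = smooth_3x3(rgb, config.render.pad_mode)
        _mark("smooth_3x3", pad_mode=config.render.pad_mode)
    if config.render.equalize:
        rgb = equalize_histogram(rgb, config.render.equalize_exclude_white)
        _mark("equalize", exclude_white=config.render.equalize_exclude_white)

    provenance = {
        "config_hash": config.config_hash,
        "seed": int(seed),
        "modality": modality,
        "steps": steps,
    }
    image = SRHImage(rgb=rgb, provenance=provenance)
    return (image, inter) if save_intermediates else image
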