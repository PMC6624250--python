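"""Readers, writers and the YAML configuration schema.

Tiles travel as per-tile multichannel OME-TIFFs named
``tile_r{row}_c{col}.ome.tif`` next to an ``index.json`` describing the grid
(rows, columns, tile size, channel names, pixel size, modality). Final SRH
renderings are written as lossless 8-bit RGB TIFF or PNG with a JSON
provenance sidecar (config hash, seed, ordered stage list). All writes are
atomic: data goes to a temporary file in the target directory which is then
renamed over the destination.

The pipeline configuration is strict YAML: unknown keys anywhere are
rejected with their dotted path, and exactly one of the ``phantom`` block or
``tiles.dir`` must be present.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .acquisition import MODALITIES, AcquisitionParams, CalibrationRecord
from .channels import QUANTIZE_MODES
from .composite import SRHImage
from .errors import CompletenessError, ConfigError, GeometryError, SchemaError
from .lut import FAMILIES, LUT, build_lut, load_lut_csv
from .mosaic import GridFilterParams, TileGrid
from .phantom import PhantomParams
from .render import RenderParams
from .stack import CARS, KNOWN_CHANNELS, TPEF, ChannelStack

INDEX_NAME = "index.json"


# ---------------------------------------------------------------------------
# atomic write helper

def _atomic_write(path: Path, write_fn) -> None:
    """Run ``write_fn(tmp_path)`` then rename tmp over `path`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=path.suffix)
    os.close(fd)
    try:
        write_fn(Path(tmp))
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_write_text(path: Path, text: str) -> None:
    _atomic_write(path, lambda p: p.write_text(text))


# ---------------------------------------------------------------------------
# tile directories

def _tile_name(r: int, c: int) -> str:
    return f"tile_r{r}_c{c}.ome.tif"


def write_tile_directory(grid: TileGrid, path) -> Path:
    """Write a grid of ChannelStack tiles as OME-TIFFs plus index.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    first = grid.tiles[(0, 0)]
    if not isinstance(first, ChannelStack):
        raise SchemaError("write_tile_directory expects ChannelStack tiles")
    names = list(first.names)
    for (r, c), tile in sorted(grid.tiles.items()):
        data = np.stack([tile[n] for n in names]).astype(np.float32)
        px = tile.pixel_size_um

        def _write(tmp, data=data, px=px):
            tifffile.imwrite(
                tmp,
                data,
                ome=True,
                metadata={
                    "axes": "CYX",
                    "Channel": {"Name": names},
                    "PhysicalSizeX": px,
                    "PhysicalSizeXUnit": "µm",
                    "PhysicalSizeY": px,
                    "PhysicalSizeYUnit": "µm",
                },
            )

        _atomic_write(path / _tile_name(r, c), _write)
    index = {
        "n_rows": grid.n_rows,
        "n_cols": grid.n_cols,
        "tile_px": grid.tile_px,
        "overlap_px": grid.overlap_px,
        "channels": names,
        "pixel_size_um": first.pixel_size_um,
        "modality": first.modality,
    }
    _atomic_write_text(path / INDEX_NAME, json.dumps(index, indent=2))
    return path


def read_tile_directory(path) -> TileGrid:
    """Read a tile directory written by :func:`write_tile_directory`."""
    path = Path(path)
    index_path = path / INDEX_NAME
    if not index_path.exists():
        raise CompletenessError(f"no {INDEX_NAME} in {path}")
    index = json.loads(index_path.read_text())
    try:
        n_rows, n_cols = int(index["n_rows"]), int(index["n_cols"])
        tile_px = int(index["tile_px"])
        names = list(index["channels"])
        pixel_size = float(index["pixel_size_um"])
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"malformed {INDEX_NAME}: {exc}") from exc
    unknown = [n for n in names if n not in KNOWN_CHANNELS]
    if unknown:
        raise SchemaError(
            f"unknown channel names {unknown} in index; expected among {list(KNOWN_CHANNELS)}"
        )
    tiles: Dict[Tuple[int, int], ChannelStack] = {}
    for r in range(n_rows):
        for c in range(n_cols):
            f = path / _tile_name(r, c)
            if not f.exists():
                raise CompletenessError(f"tile ({r}, {c}) listed in index but {f.name} is absent")
            data = np.asarray(tifffile.imread(f))
            if data.ndim == 2:
                data = data[None]
            if data.shape[0] != len(names):
                raise SchemaError(
                    f"{f.name} has {data.shape[0]} planes but index lists {len(names)} channels"
                )
            if data.shape[1:] != (tile_px, tile_px):
                raise GeometryError(
                    f"{f.name} has shape {data.shape[1:]}, index says {(tile_px, tile_px)}"
                )
            tiles[(r, c)] = ChannelStack(
                channels={n: data[i].astype(np.float64) for i, n in enumerate(names)},
                pixel_size_um=pixel_size,
                modality=index.get("modality"),
            )
    return TileGrid(
        tiles=tiles,
        n_rows=n_rows,
        n_cols=n_cols,
        tile_px=tile_px,
        overlap_px=int(index.get("overlap_px", 0)),
    )


def write_mosaic_stack(stack: ChannelStack, path) -> Path:
    """Write a stitched multichannel stack as one OME-TIFF."""
    path = Path(path)
    names = list(stack.names)
    data = np.stack([stack[n] for n in names]).astype(np.float32)

    def _write(tmp):
        tifffile.imwrite(
            tmp,
            data,
            ome=True,
            metadata={
                "axes": "CYX",
                "Channel": {"Name": names},
                "PhysicalSizeX": stack.pixel_size_um,
                "PhysicalSizeXUnit": "µm",
                "PhysicalSizeY": stack.pixel_size_um,
                "PhysicalSizeYUnit": "µm",
            },
        )

    _atomic_write(path, _write)
    return path


# ---------------------------------------------------------------------------
# ground-truth export

def export_truth(truth, path_prefix) -> Tuple[Path, Path]:
    """Export GroundTruthMaps as a multi-page TIFF plus a JSON sidecar."""
    path_prefix = Path(path_prefix)
    tif = path_prefix.with_suffix(".tif")
    sidecar = path_prefix.with_suffix(".json")
    stackdata = np.stack(
        [truth.cellbody_density, truth.nuclei_density, truth.collagen_density]
    ).astype(np.float32)
    _atomic_write(tif, lambda tmp: tifffile.imwrite(tmp, stackdata, metadata={"axes": "CYX"}))
    meta = {
        "planes": ["cellbody_density", "nuclei_density", "collagen_density"],
        "pixel_size_um": truth.pixel_size_um,
        "nuclei_centroids": [list(map(int, rc)) for rc in truth.nuclei_centroids],
        "gland_outlines": [v.tolist() for v in truth.gland_outlines],
    }
    _atomic_write_text(sidecar, json.dumps(meta))
    return tif, sidecar


# ---------------------------------------------------------------------------
# final SRH image

def write_srh(image: SRHImage, path, format: Optional[str] = None) -> Tuple[Path, Path]:
    """Write a lossless 8-bit RGB rendering plus its provenance sidecar.

    Returns (image path, sidecar path). ``format`` defaults to the file
    suffix ('tiff' or 'png').
    """
    path = Path(path)
    if format is None:
        format = "tiff" if path.suffix.lower() in (".tif", ".tiff") else "png"
    if format not in ("tiff", "png"):
        raise ConfigError(f"unsupported output format {format!r}")
    if format == "tiff":
        _atomic_write(path, lambda tmp: tifffile.imwrite(tmp, image.rgb, photometric="rgb"))
    else:
        _atomic_write(path, lambda tmp: iio.imwrite(tmp, image.rgb, extension=".png"))
    sidecar = path.with_suffix(path.suffix + ".json")
    _atomic_write_text(sidecar, json.dumps(image.provenance, indent=2, sort_keys=True))
    return path, sidecar


def read_srh(path) -> np.ndarray:
    """Read back an SRH rendering as an (H, W, 3) uint8 array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path))
    return np.asarray(iio.imread(path))[..., :3]


# ---------------------------------------------------------------------------
# configuration

@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see the YAML schema in README)."""

    seed: int = 0
    out_dir: Optional[Path] = None
    phantom: Optional[PhantomParams] = None
    phantom_seed_explicit: bool = False
    blur_sigma_um: float = 0.0
    tile_dir: Optional[Path] = None
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    calibration: Optional[CalibrationRecord] = None
    k_collagen: float = 1.0
    k_nuclei: float = 1.0
    k_cellbody: float = 1.0
    quant_mode: str = "percentile"
    p_low: float = 1.0
    p_high: float = 99.0
    cellbody_source: str = TPEF
    per_tile_mean: bool = False
    lut_shg: LUT = field(default_factory=lambda: build_lut("saffron"))
    lut_nuclei: LUT = field(default_factory=lambda: build_lut("hematoxylin"))
    lut_cellbody: LUT = field(default_factory=lambda: build_lut("eosin"))
    grid_filter_enabled: bool = True
    grid_filter: GridFilterParams = field(default_factory=GridFilterParams)
    render: RenderParams = field(default_factory=RenderParams)
    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.phantom is None) == (self.tile_dir is None):
            raise ConfigError("exactly one of the phantom block and tiles.dir must be set")
        if self.quant_mode not in QUANTIZE_MODES:
            raise ConfigError(f"channels.quantize.mode must be one of {QUANTIZE_MODES}")
        if self.cellbody_source not in (TPEF, CARS):
            raise ConfigError("channels.cellbody_source must be TPEF or CARS")

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


class _Section:
    """A strict dict view that records its dotted path and consumed keys."""

    def __init__(self, data: dict, path: str):
        if not isinstance(data, dict):
            raise ConfigError(f"config section {path or '<root>'} must be a mapping")
        self.data = dict(data)
        self.path = path

    def take(self, key, default=None):
        return self.data.pop(key, default)

    def has(self, key) -> bool:
        return key in self.data

    def section(self, key) -> Optional["_Section"]:
        val = self.data.pop(key, None)
        if val is None:
            return None
        return _Section(val, f"{self.path}.{key}" if self.path else key)

    def finish(self) -> None:
        if self.data:
            where = self.path or "<root>"
            raise ConfigError(f"unknown config key(s) {sorted(self.data)} in {where}")


def parse_config(data: dict, base_dir: Optional[Path] = None) -> PipelineConfig:
    """Validate a raw config mapping into a :class:`PipelineConfig`."""
    base_dir = Path(base_dir) if base_dir is not None else Path.cwd()
    raw = json.loads(json.dumps(data))  # normalized copy for hashing
    root = _Section(data, "")

    seed = int(root.take("seed", 0))
    out_dir = root.take("out_dir")
    out_dir = (base_dir / out_dir) if out_dir else None

    phantom = None
    phantom_seed_explicit = False
    blur_sigma_um = 0.0
    ph = root.section("phantom")
    if ph is not None:
        grade = ph.take("grade", "healthy")
        blur_sigma_um = float(ph.take("blur_sigma_um", 0.0))
        phantom_seed_explicit = ph.has("seed")
        known = {
            "field_size_um", "pixel_size_um", "crypt_diameter_mean_um",
            "crypt_diameter_cv", "crypt_density_per_mm2", "nuclei_per_crypt",
            "nucleus_diameter_um", "vacuole_fraction", "collagen_fiber_density",
            "fibrosis_factor", "pseudostratification", "nc_ratio",
            "stroma_density", "epithelium_density", "seed",
        }
        overrides = {k: ph.take(k) for k in list(ph.data) if k in known}
        ph.finish()
        try:
            phantom = PhantomParams.preset(grade, **overrides)
        except TypeError as exc:
            raise ConfigError(f"bad phantom block: {exc}") from exc

    tile_dir = None
    tiles = root.section("tiles")
    if tiles is not None:
        d = tiles.take("dir")
        tiles.finish()
        if d is None:
            raise ConfigError("tiles block needs a 'dir' entry")
        tile_dir = base_dir / d

    acq_kwargs = {}
    calibration = None
    acq = root.section("acquisition")
    if acq is not None:
        cal = acq.section("calibration")
        if cal is not None:
            calibration = CalibrationRecord(
                reference_signal=float(cal.take("reference_signal")),
                reference_nominal=float(cal.take("reference_nominal", 1.0)),
            )
            cal.finish()
        known = {
            "modality", "tile_px", "tile_um", "dwell_us", "accumulations",
            "noise_sigma", "gain_2845", "gain_2930", "modulation_freq_hz",
            "samples_per_pixel", "seed",
        }
        acq_kwargs = {k: acq.take(k) for k in list(acq.data) if k in known}
        acq.finish()
    acquisition = AcquisitionParams(**acq_kwargs)
    if acquisition.modality not in MODALITIES:
        raise ConfigError(f"acquisition.modality must be one of {MODALITIES}")

    k_collagen = k_nuclei = k_cellbody = 1.0
    quant_mode, p_low, p_high = "percentile", 1.0, 99.0
    cellbody_source, per_tile_mean = TPEF, False
    ch = root.section("channels")
    if ch is not None:
        k_collagen = float(ch.take("k_collagen", 1.0))
        k_nuclei = float(ch.take("k_nuclei", 1.0))
        k_cellbody = float(ch.take("k_cellbody", 1.0))
        cellbody_source = str(ch.take("cellbody_source", TPEF))
        per_tile_mean = bool(ch.take("per_tile_mean", False))
        qz = ch.section("quantize")
        if qz is not None:
            quant_mode = str(qz.take("mode", "percentile"))
            p_low = float(qz.take("p_low", 1.0))
            p_high = float(qz.take("p_high", 99.0))
            qz.finish()
        ch.finish()

    def _lut_for(sec: Optional[_Section], default_family: str) -> LUT:
        if sec is None:
            return build_lut(default_family)
        palette = sec.take("palette")
        family = str(sec.take("family", default_family))
        variant = int(sec.take("variant", 0))
        sec.finish()
        if family not in FAMILIES:
            raise ConfigError(f"lut family must be one of {FAMILIES}, got {family!r}")
        if palette is not None:
            return load_lut_csv(base_dir / palette, family=family, variant=variant)
        return build_lut(family, variant)

    lut_block = root.section("lut")
    if lut_block is not None:
        lut_shg = _lut_for(lut_block.section("shg"), "saffron")
        lut_nuclei = _lut_for(lut_block.section("nuclei"), "hematoxylin")
        lut_cellbody = _lut_for(lut_block.section("cellbody"), "eosin")
        lut_block.finish()
    else:
        lut_shg = build_lut("saffron")
        lut_nuclei = build_lut("hematoxylin")
        lut_cellbody = build_lut("eosin")

    grid_filter_enabled = True
    grid_filter = GridFilterParams()
    mo = root.section("mosaic")
    if mo is not None:
        gf = mo.section("grid_filter")
        if gf is not None:
            grid_filter_enabled = bool(gf.take("enabled", True))
            clip = gf.take("intensity_clip")
            harmonics = gf.take("harmonics")
            grid_filter = GridFilterParams(
                notch_radius_bins=float(gf.take("notch_radius_bins", 1.5)),
                harmonics=int(harmonics) if harmonics is not None else None,
                notch_depth=float(gf.take("notch_depth", 1.0)),
                intensity_clip=tuple(clip) if clip is not None else None,
            )
            gf.finish()
        mo.finish()

    render = RenderParams()
    re_sec = root.section("render")
    if re_sec is not None:
        render = RenderParams(
            smooth=bool(re_sec.take("smooth", True)),
            equalize=bool(re_sec.take("equalize", False)),
            pad_mode=str(re_sec.take("pad_mode", "replicate")),
            equalize_exclude_white=bool(re_sec.take("equalize_exclude_white", True)),
        )
        re_sec.finish()

    root.finish()
    return PipelineConfig(
        seed=seed,
        out_dir=out_dir,
        phantom=phantom,
        phantom_seed_explicit=phantom_seed_explicit,
        blur_sigma_um=blur_sigma_um,
        tile_dir=tile_dir,
        acquisition=acquisition,
        calibration=calibration,
        k_collagen=k_collagen,
        k_nuclei=k_nuclei,
        k_cellbody=k_cellbody,
        quant_mode=quant_mode,
        p_low=p_low,
        p_high=p_high,
        cellbody_source=cellbody_source,
        per_tile_mean=per_tile_mean,
        lut_shg=lut_shg,
        lut_nuclei=lut_nuclei,
        lut_cellbody=lut_cellbody,
        grid_filter_enabled=grid_filter_enabled,
        grid_filter=grid_filter,
        render=render,
        raw=raw,
    )


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration file."""
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if data is None:
        raise ConfigError(f"{path} is empty")
    return parse_config(data, base_dir=path.parent)
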