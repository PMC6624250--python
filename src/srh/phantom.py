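"""Synthetic gastro-intestinal tissue phantoms.

Generates noiseless ground-truth density maps of colon mucosa so the whole
virtual-coloring pipeline can be exercised and validated without patient
data. Three morphological grades are modelled:

``healthy``
    The "daisy field": round crypts of Lieberkuehn ~100 um in diameter,
    nuclei regularly spaced around the gland rim in basal position, a central
    mucus vacuole (a zero-density lumen) inside each crypt.
``low_grade_dysplasia``
    Enlarged (default 1.8x) elliptical/irregular glands, two concentric rows
    of rim nuclei (pseudostratification), reduced vacuole fraction.
``adenocarcinoma``
    Sparse, angulated glands, raised nucleocytoplasmic ratio (larger nuclei),
    near-absent lumina, and stromal collagen fibrosis concentrated around the
    gland contours.

Geometry is intentionally schematic: glands are low-order radial-Fourier
perturbations of circles/ellipses, nuclei are filled discs, collagen fibres
are thin rectangles. The point is to expose the *contrasts* the downstream
stages must render (gland size, nuclear crowding, vacuole loss, fibrosis),
not histologically faithful texture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.draw import disk as _draw_disk
from skimage.draw import polygon as _draw_polygon

from ._util import derive_seed
from .errors import PackingError, ParameterError, SizingError
from .stack import CARS, SHG, SRS2845, SRS2930, TPEF, ChannelStack

GRADES = ("healthy", "low_grade_dysplasia", "adenocarcinoma")

#: Nucleocytoplasmic ratio at which the configured nucleus diameter is drawn
#: unscaled; other ratios scale the drawn diameter by sqrt(nc_ratio / this).
REFERENCE_NC_RATIO = 0.2

EPITHELIUM_DENSITY_DEFAULT = 1.0
STROMA_DENSITY_DEFAULT = 0.25
NUCLEUS_DENSITY = 1.0
FIBER_DENSITY = 0.8
SHEATH_DENSITY = 0.5

_OUTLINE_VERTICES = 96
_REJECTION_CAP_FACTOR = 50  # attempts per requested crypt before giving up
_MIN_RASTER_PX = 64

_PRESETS: Dict[str, dict] = {
    "healthy": dict(
        crypt_diameter_mean_um=100.0,
        crypt_diameter_cv=0.10,
        crypt_density_per_mm2=25.0,
        nuclei_per_crypt=16,
        nucleus_diameter_um=6.0,
        vacuole_fraction=0.45,
        collagen_fiber_density=5.0,
        fibrosis_factor=1.0,
        pseudostratification=False,
        nc_ratio=0.2,
    ),
    "low_grade_dysplasia": dict(
        crypt_diameter_mean_um=180.0,
        crypt_diameter_cv=0.25,
        crypt_density_per_mm2=10.0,
        nuclei_per_crypt=36,
        nucleus_diameter_um=6.0,
        vacuole_fraction=0.10,
        collagen_fiber_density=5.0,
        fibrosis_factor=1.0,
        pseudostratification=True,
        nc_ratio=0.3,
    ),
    "adenocarcinoma": dict(
        crypt_diameter_mean_um=150.0,
        crypt_diameter_cv=0.35,
        crypt_density_per_mm2=6.0,
        nuclei_per_crypt=40,
        nucleus_diameter_um=6.0,
        vacuole_fraction=0.02,
        collagen_fiber_density=15.0,
        fibrosis_factor=3.0,
        pseudostratification=False,
        nc_ratio=0.55,
    ),
}


@dataclass(frozen=True)
class PhantomParams:
    """Knobs of the tissue phantom. Defaults are the healthy-colon preset.

    Use :meth:`preset` to start from a grade's preset and override
    individual knobs explicitly.
    """

    grade: str = "healthy"
    field_size_um: float = 500.0
    pixel_size_um: float = 0.5
    crypt_diameter_mean_um: float = 100.0
    crypt_diameter_cv: float = 0.10
    crypt_density_per_mm2: float = 25.0
    nuclei_per_crypt: int = 16
    nucleus_diameter_um: float = 6.0
    vacuole_fraction: float = 0.45
    collagen_fiber_density: float = 5.0
    fibrosis_factor: float = 1.0
    pseudostratification: bool = False
    nc_ratio: float = 0.2
    stroma_density: float = STROMA_DENSITY_DEFAULT
    epithelium_density: float = EPITHELIUM_DENSITY_DEFAULT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grade not in GRADES:
            raise ParameterError(f"unknown grade {self.grade!r}; expected one of {GRADES}")
        for name in ("field_size_um", "pixel_size_um", "crypt_diameter_mean_um", "nucleus_diameter_um"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not 0 <= self.crypt_diameter_cv < 1:
            raise ParameterError("crypt_diameter_cv must be in [0, 1)")
        if self.crypt_density_per_mm2 < 0:
            raise ParameterError("crypt_density_per_mm2 must be nonnegative")
        if self.nuclei_per_crypt < 0:
            raise ParameterError("nuclei_per_crypt must be nonnegative")
        if not 0 <= self.vacuole_fraction <= 1:
            raise ParameterError("vacuole_fraction must be in [0, 1]")
        if self.collagen_fiber_density < 0 or self.fibrosis_factor < 0:
            raise ParameterError("collagen_fiber_density and fibrosis_factor must be nonnegative")
        if not 0 < self.nc_ratio <= 1:
            raise ParameterError("nc_ratio must be in (0, 1]")
        if self.stroma_density < 0 or self.epithelium_density < 0:
            raise ParameterError("densities must be nonnegative")

    @classmethod
    def preset(cls, grade: str, **overrides) -> "PhantomParams":
        """Build params from a grade preset; explicit overrides win."""
        if grade not in _PRESETS:
            raise ParameterError(f"unknown grade {grade!r}; expected one of {GRADES}")
        values = dict(_PRESETS[grade])
        values.update(overrides)
        return cls(grade=grade, **values)


@dataclass
class GroundTruthMaps:
    """Noiseless density rasters plus the geometric truth used to draw them."""

    cellbody_density: np.ndarray
    nuclei_density: np.ndarray
    collagen_density: np.ndarray
    nuclei_centroids: List[Tuple[int, int]]
    gland_outlines: List[np.ndarray]  # each (K, 2) float array of (row, col) px
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        shapes = {
            self.cellbody_density.shape,
            self.nuclei_density.shape,
            self.collagen_density.shape,
        }
        if len(shapes) != 1:
            raise SizingError("ground-truth rasters must share one shape")
        h, w = self.cellbody_density.shape
        for r, c in self.nuclei_centroids:
            if not (0 <= r < h and 0 <= c < w):
                raise SizingError(f"nucleus centroid {(r, c)} lies outside the raster")

    @property
    def shape(self) -> tuple:
        return self.cellbody_density.shape


def _sample_diameter(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Normal(mean, cv*mean) truncated at +/- 2 sigma by resampling."""
    if cv == 0:
        return mean
    sd = cv * mean
    while True:
        d = rng.normal(mean, sd)
        if abs(d - mean) <= 2.0 * sd:
            return max(d, 1e-6)


def _gland_radii(rng: np.random.Generator, grade: str, r0_px: float) -> np.ndarray:
    """Radial profile r(theta) of one gland outline, in pixels."""
    theta = np.linspace(0.0, 2.0 * np.pi, _OUTLINE_VERTICES, endpoint=False)
    if grade == "healthy":
        r = np.full_like(theta, r0_px)
    else:
        if grade == "low_grade_dysplasia":
            axis_ratio = rng.uniform(1.3, 2.5)
            orders, amp_hi = (2, 3), 0.08
        else:  # adenocarcinoma: angulated contours
            axis_ratio = rng.uniform(1.2, 2.0)
            orders, amp_hi = (3, 4, 5, 6), 0.22
        rot = rng.uniform(0.0, 2.0 * np.pi)
        a = r0_px * math.sqrt(axis_ratio)
        b = r0_px / math.sqrt(axis_ratio)
        r = a * b / np.sqrt((b * np.cos(theta - rot)) ** 2 + (a * np.sin(theta - rot)) ** 2)
        for k in orders:
            amp = rng.uniform(0.02, amp_hi)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            r = r * (1.0 + amp * np.cos(k * theta + phase))
    return r


def _outline_vertices(center: np.ndarray, radii: np.ndarray) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * np.pi, len(radii), endpoint=False)
    return np.stack(
        [center[0] + radii * np.sin(theta), center[1] + radii * np.cos(theta)], axis=1
    )


def _fill_outline(verts: np.ndarray, shape: tuple, scale: float = 1.0, center: Optional[np.ndarray] = None) -> np.ndarray:
    """Boolean raster of the (optionally rescaled-about-center) polygon."""
    if scale != 1.0:
        assert center is not None
        verts = center + scale * (verts - center)
    mask = np.zeros(shape, dtype=bool)
    rr, cc = _draw_polygon(verts[:, 0], verts[:, 1], shape=shape)
    mask[rr, cc] = True
    return mask


def generate_phantom(params: PhantomParams) -> GroundTruthMaps:
    """Draw the ground-truth density maps for one square tissue field.

    Crypts are placed by rejection sampling without overlap; the sampler
    gives up (``PackingError``) after 50 attempts per requested crypt, which
    in practice flags densities beyond loose circle packing.
    """
    n_px_f = params.field_size_um / params.pixel_size_um
    if abs(n_px_f - round(n_px_f)) > 1e-6:
        raise SizingError(
            f"field_size_um / pixel_size_um = {n_px_f} is not an integer pixel count"
        )
    n_px = int(round(n_px_f))
    if n_px < _MIN_RASTER_PX:
        raise SizingError(f"raster of {n_px} px per side is below the {_MIN_RASTER_PX} px minimum")

    rng = np.random.default_rng(params.seed)
    shape = (n_px, n_px)
    px = params.pixel_size_um
    area_mm2 = (params.field_size_um / 1000.0) ** 2
    n_crypts = int(round(params.crypt_density_per_mm2 * area_mm2))

    # --- place gland outlines ---------------------------------------------
    glands: List[dict] = []
    attempts = 0
    cap = _REJECTION_CAP_FACTOR * max(n_crypts, 1)
    while len(glands) < n_crypts:
        attempts += 1
        if attempts > cap:
            raise PackingError(
                f"could not place {n_crypts} crypts (density "
                f"{params.crypt_density_per_mm2}/mm^2) after {cap} attempts"
            )
        d_um = _sample_diameter(rng, params.crypt_diameter_mean_um, params.crypt_diameter_cv)
        radii = _gland_radii(rng, params.grade, (d_um / 2.0) / px)
        r_max = float(radii.max())
        margin = r_max + 2.0
        if 2.0 * margin >= n_px:
            continue
        center = rng.uniform(margin, n_px - margin, size=2)
        ok = True
        for g in glands:
            if np.hypot(*(center - g["center"])) <= r_max + g["r_max"] + 4.0:
                ok = False
                break
        if ok:
            glands.append({"center": center, "radii": radii, "r_max": r_max})

    # a field with no glands is a bare slide: no stromal background either
    cellbody = (
        np.full(shape, params.stroma_density, dtype=np.float64)
        if glands
        else np.zeros(shape, dtype=np.float64)
    )
    nuclei = np.zeros(shape, dtype=np.float64)
    collagen = np.zeros(shape, dtype=np.float64)
    centroids: List[Tuple[int, int]] = []
    outlines: List[np.ndarray] = []

    nucleus_d_px = params.nucleus_diameter_um * math.sqrt(params.nc_ratio / REFERENCE_NC_RATIO) / px
    nucleus_r_px = max(nucleus_d_px / 2.0, 0.6)

    gland_masks: List[np.ndarray] = []
    for g in glands:
        verts = _outline_vertices(g["center"], g["radii"])
        outlines.append(verts)
        mask = _fill_outline(verts, shape)
        gland_masks.append(mask)
        cellbody[mask] = params.epithelium_density
        if params.vacuole_fraction > 0:
            vac = _fill_outline(verts, shape, scale=math.sqrt(params.vacuole_fraction), center=g["center"])
            cellbody[vac] = 0.0

        # basal nuclei on the gland rim; a second concentric row when
        # pseudostratified (1.5 nucleus diameters further inward)
        n_total = params.nuclei_per_crypt
        if n_total > 0:
            rows: List[Tuple[int, float, float]] = []  # (count, extra inward px, phase)
            if params.pseudostratification and n_total >= 2:
                n_outer = (n_total + 1) // 2
                rows.append((n_outer, 0.0, rng.uniform(0, 2 * np.pi)))
                rows.append((n_total - n_outer, 1.5 * nucleus_d_px, rng.uniform(0, 2 * np.pi)))
            else:
                rows.append((n_total, 0.0, rng.uniform(0, 2 * np.pi)))
            theta_grid = np.linspace(0.0, 2.0 * np.pi, _OUTLINE_VERTICES, endpoint=False)
            for count, inward, phase in rows:
                for i in range(count):
                    th = (phase + 2.0 * np.pi * i / count) % (2.0 * np.pi)
                    r_th = np.interp(th, theta_grid, g["radii"], period=2.0 * np.pi)
                    rad = max(r_th - (nucleus_r_px + 1.0) - inward, 0.0)
                    pos = g["center"] + rad * np.array([math.sin(th), math.cos(th)])
                    rr, cc = _draw_disk((pos[0], pos[1]), nucleus_r_px, shape=shape)
                    nuclei[rr, cc] = NUCLEUS_DENSITY
                    cr = int(min(max(round(pos[0]), 0), n_px - 1))
                    cc_i = int(min(max(round(pos[1]), 0), n_px - 1))
                    centroids.append((cr, cc_i))

    # --- collagen ----------------------------------------------------------
    if params.collagen_fiber_density > 0:
        n_fibers = int(round(params.collagen_fiber_density * area_mm2))
        half_w_px = max(1.0 / px, 0.75)  # ~2 um wide fibres
        for _ in range(n_fibers):
            c = rng.uniform(0, n_px, size=2)
            ang = rng.uniform(0, np.pi)
            length = rng.uniform(40.0, 150.0) / px
            d = np.array([math.sin(ang), math.cos(ang)])
            n = np.array([-d[1], d[0]]) * half_w_px
            p0, p1 = c - d * length / 2, c + d * length / 2
            quad = np.stack([p0 + n, p1 + n, p1 - n, p0 - n])
            rr, cc = _draw_polygon(quad[:, 0], quad[:, 1], shape=shape)
            collagen[rr, cc] = np.maximum(collagen[rr, cc], FIBER_DENSITY)
        # thin periglandular collagen sheath (muscularis propria analogue)
        for g, verts, mask in zip(glands, outlines, gland_masks):
            sheath = _fill_outline(verts, shape, scale=1.08, center=g["center"]) & ~mask
            collagen[sheath] = np.maximum(collagen[sheath], SHEATH_DENSITY)
        if params.fibrosis_factor != 1.0:
            for g, verts, mask in zip(glands, outlines, gland_masks):
                band = _fill_outline(verts, shape, scale=1.3, center=g["center"]) & ~mask
                collagen[band] *= params.fibrosis_factor

    return GroundTruthMaps(
        cellbody_density=cellbody,
        nuclei_density=nuclei,
        collagen_density=collagen,
        nuclei_centroids=centroids,
        gland_outlines=outlines,
        pixel_size_um=px,
    )


def rasterize_channels(truth: GroundTruthMaps, blur_sigma_um: float = 0.0) -> ChannelStack:
    """Map ground truth onto the four physical channels.

    SRS2845 and the auxiliary TPEF/CARS channels see cell bodies, SRS2930
    sees cell bodies plus nuclei (so the downstream subtraction recovers the
    nuclei), SHG sees collagen. An optional Gaussian blur emulates the finite
    focal spot.
    """
    if blur_sigma_um < 0:
        raise ParameterError("blur_sigma_um must be nonnegative")
    channels = {
        SRS2845: truth.cellbody_density.copy(),
        SRS2930: truth.cellbody_density + truth.nuclei_density,
        SHG: truth.collagen_density.copy(),
        TPEF: truth.cellbody_density.copy(),
        CARS: truth.cellbody_density.copy(),
    }
    sigma_px = blur_sigma_um / truth.pixel_size_um
    if sigma_px > 0:
        channels = {k: ndimage.gaussian_filter(v, sigma_px) for k, v in channels.items()}
    return ChannelStack(channels=channels, pixel_size_um=truth.pixel_size_um, modality=None)


# ---------------------------------------------------------------------------
# measurement helpers (used by tests and the acceptance script)

def equivalent_circle_diameters_um(truth: GroundTruthMaps) -> np.ndarray:
    """Equivalent-circle diameter of every gland outline, in micrometres."""
    diams = []
    for verts in truth.gland_outlines:
        r, c = verts[:, 0], verts[:, 1]
        area_px = 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))
        diams.append(2.0 * math.sqrt(area_px / math.pi) * truth.pixel_size_um)
    return np.asarray(diams)


def vacuole_pixel_count(truth: GroundTruthMaps) -> int:
    """Pixels with zero cell-body density inside gland outlines (the lumina)."""
    shape = truth.shape
    inside = np.zeros(shape, dtype=bool)
    for verts in truth.gland_outlines:
        rr, cc = _draw_polygon(verts[:, 0], verts[:, 1], shape=shape)
        inside[rr, cc] = True
    return int(np.count_nonzero(inside & (truth.cellbody_density == 0)))


def count_nuclei_components(truth: GroundTruthMaps) -> int:
    """Connected components of the nuclei raster (4-connectivity)."""
    labeled, n = ndimage.label(truth.nuclei_density > 0)
    return int(n)
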