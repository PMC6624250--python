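# Methods

`srh` simulates and processes label-free nonlinear-microscopy data into
virtually stained histology images. The pipeline mirrors the workflow of a
stimulated-Raman-histology (SRH) instrument: multichannel tiles are acquired
(or simulated), stitched into a millimetre-scale mosaic, recolored with
stain-mimicking lookup tables, composited by per-pixel priority, cleaned of
the stitching grid in the Fourier plane, and finished with smoothing and
optional histogram equalization.

## Signal model

Four physical channels are modelled, each a nonnegative 2-D raster in
arbitrary units (a.u.):

| channel | contrast | virtual stain |
|---|---|---|
| SRS at 2845 cm⁻¹ (CH₂) | cell bodies / lipids | eosin (pink) |
| SRS at 2930 cm⁻¹ (CH₃) | cell bodies + nuclei / proteins | — (nuclei derived) |
| SRS_nuclei = SRS₂₉₃₀ − SRS₂₈₄₅ | cell nuclei | hematoxylin (dark purple) |
| SHG | fibrillar collagen | saffron (orange) |
| TPEF / CARS | cell bodies (FM-SRS mode) | eosin |

### λ-switch acquisition

The two pump wavelengths are shuttered alternately, so SRS₂₈₄₅ and SRS₂₉₃₀
come from separate raster passes. Each measured channel is
`gain · truth + ε̄`, where `ε̄` is the arithmetic mean of `accumulations`
independent zero-mean Gaussian noise frames of standard deviation
`noise_sigma` (a.u.). Averaging (rather than summing) accumulations keeps
the grey scale independent of the accumulation count; with the default 3
accumulations the per-pixel noise std is `noise_sigma/√3`. Defaults follow
the instrument geometry: 200 × 200 px tiles covering 100 µm × 100 µm, 40 µs
pixel dwell, 3 accumulations.

Additive Gaussian noise is the only detector model; shot-noise scaling and
laser intensity noise are not modelled — `noise_sigma` is a single knob.

### FM-SRS acquisition

Both pumps are square-wave modulated (acousto-optic modulators gate the
beams on/off at 20 MHz, 50% duty) with a 180° relative phase. The Stokes
gain time series during one pixel dwell is

    s(t) = g₂₉₃₀·I₂₉₃₀·m(t) + g₂₈₄₅·I₂₈₄₅·m(t + T/2) + ε(t),

with `m` the unit square wave and `T` its period. Lock-in demodulation
multiplies by the zero-mean reference `r(t) = 2m(t) − 1` (in phase with the
2930 pump), averages over the dwell, and normalizes by the
reference–modulation overlap `⟨r·m⟩ = 1/2`, giving directly

    FMSRS = g₂₉₃₀·I₂₉₃₀ − g₂₈₄₅·I₂₈₄₅.

Implementation note: the demodulated value is evaluated through exact inner
products of one dwell's synthesized waveforms (O(1) per pixel), and the
demodulated detector noise is drawn in closed form as the Gaussian
projection of per-sample noise onto the reference,
`N(0, noise_sigma/√samples_per_pixel)` per accumulation. This is identical
in distribution to materializing the per-pixel time series; the test suite
cross-checks single pixels against a full numerical time-series lock-in.
Sampling must tile an integer number of modulation periods with an even
sample count per period, otherwise the demodulation sums are biased and a
sampling error is raised. The default 6400 samples/pixel gives 8 samples
per each of the 800 periods in a 40 µs dwell.

Daily pump-power drift is corrected by a multiplicative oil-reference
calibration at 2930 cm⁻¹: `channel · reference_nominal / reference_signal`.

## Virtual HES coloring

1. **Nuclei derivation.** λ-switch: element-wise subtraction
   SRS₂₉₃₀ − SRS₂₈₄₅, negatives clipped to 0 (the nuclei signal is
   physically nonnegative). FM-SRS: the demodulated channel, clipped the
   same way. Subtraction happens on calibrated floating-point values before
   quantization to avoid 8-bit rounding bias.
2. **Quantization.** Each derived channel is affinely mapped onto the
   [0, 255] grey scale, either over its min–max range or a percentile
   window (default 1–99, robust to hot pixels). A constant raster maps to
   all zeros. All integer rounding throughout the package is half-up.
3. **Lookup tables.** Each stain family (eosin, hematoxylin, saffron) has
   four shade variants. A table ramps piecewise-linearly per RGB channel
   from pure white at grey 0 through a midtone at grey 128 to a dark anchor
   at grey 255; the midtone is `white + s·(dark − white)` with the
   variant's saturation `s ∈ {0.35, 0.45, 0.55, 0.65}`. Because each RGB
   channel is monotone non-increasing, luminance is non-increasing even
   after rounding — stronger signal always renders darker. Default anchors
   (eosin (222, 64, 134), hematoxylin (70, 35, 90), saffron (235, 140, 30))
   are cosmetic conventions; exact palettes can be pinned via 256×3 CSV.
4. **Thresholds.** `Threshold = k · Mean` per layer, `k ∈ [0, 2]` snapped
   to 0.01 (a slider granularity). Mean is the arithmetic mean of the grey
   image, computed globally over the stitched mosaic by default (one
   threshold per layer mimics a single-slider interface); a per-tile option
   computes thresholds per 100 µm tile instead. Whether the original
   workflow used global or per-tile means is not determinable, hence both.
5. **Priority compositing.** Per pixel, strictly in order: SHG above its
   threshold → saffron pixel; else nuclei above threshold → hematoxylin
   pixel; else cell body above threshold → eosin pixel; else white.
   Comparisons are strict, so ties fall through. SHG priority exists
   because collagen appears in both the nuclei contrast and SHG; SHG
   disambiguates it. No blending is performed.

## Mosaic and grid removal

Tiles abut with zero overlap (motorized-stage stitching); stitching is pure
block placement and exactly invertible. Per-tile offsets leave a periodic
seam pattern at the tile pitch. Each RGB channel of the composited mosaic
is FFT-filtered with a fixed mask of Gaussian notches at the grid's
spatial-frequency harmonics `k/tile_px` cycles/px. Because the seams are
only ~2 px wide their comb spectrum extends to high orders, so the default
notches **all** harmonics up to the Nyquist of the tile pitch, on both
frequency axes plus the low-order diagonal crossings; an explicit
`harmonics: k` limits the comb. Notches use Gaussian attenuation
(default radius 1.5 bins, depth 1.0) rather than hard zeroing to avoid
ringing; the DC bin is preserved exactly, so channel means are unchanged.
A configuration whose notch centers fall within one radius of DC is
rejected. Optional per-channel percentile clamping ("intensity filtering")
runs after the inverse transform. Measured on a synthetic 4×4 mosaic with
2-px seams: ≥ 20 dB (typically ~60 dB) attenuation at the seam harmonics,
while seam-free broadband textures retain Pearson r ≈ 0.996.

## Final rendering

* **3×3 smoothing**: each pixel replaced by 1/9 of its 3×3 neighborhood
  sum, per channel. Border handling is replicate padding by default
  (reflect available) — the original formula is interior-only, so the
  border rule is a package choice.
* **Histogram equalization** (off by default, applied "when needed"): per
  channel, `v → round(255·(cdf(v) − cdf_min)/(1 − cdf_min))` over 256
  bins. Fully white pixels are excluded from histogram building by default
  and pass through unchanged, so large empty-slide areas cannot dominate
  the cdf and wash out stain contrast. A single-level channel maps to 0 by
  convention.

## Tissue phantom

The phantom generates ground-truth density maps (cell body, nuclei,
collagen) plus the geometry used to draw them (gland outlines, nucleus
centroids), so every downstream claim can be checked against known truth.

* **Healthy colon**: circular crypts, diameter ~ Normal(100 µm, cv 10%)
  truncated at ±2σ, placed without overlap by rejection sampling (50
  attempts per requested crypt before a packing error); default density
  25 crypts/mm². Each crypt has a central mucus vacuole — a zero-density
  lumen whose area is `vacuole_fraction` (0.45) of the gland — and 16
  nuclei (6 µm discs) equally spaced just inside the rim (basal position).
* **Low-grade dysplasia**: 1.8× enlarged elliptical glands (axis ratio
  1.3–2.5) with low-order radial-Fourier irregularity, vacuole fraction
  reduced to 0.10, and two concentric nucleus rows (pseudostratification,
  second row 1.5 nucleus diameters inward). The enlargement factor is a
  free parameter — no quantitative dysplasia size distribution is
  available — defaulted to 1.8×.
* **Adenocarcinoma**: sparse angulated glands (stronger, higher-order
  contour perturbation), near-absent lumina, raised nucleocytoplasmic
  ratio (nucleus diameter scales with √(nc_ratio/0.2)), and collagen
  multiplied by `fibrosis_factor` in a band around each gland contour.

Collagen is random thin fibres (2 µm wide, 40–150 µm long) plus a thin
periglandular sheath; when `collagen_fiber_density` is 0 no collagen at
all is drawn (bare-slide behaviour). Extra knobs `stroma_density` and
`epithelium_density` let tests construct empty and nuclei-only fields.
Channel rasterization maps truth to SRS₂₈₄₅ = cell body, SRS₂₉₃₀ = cell
body + nuclei, SHG = collagen, TPEF = CARS = cell body, with an optional
shared Gaussian blur for the finite focal spot.

What the phantom does **not** emulate: real histological texture, partial
volume and depth effects, spatially varying illumination, shot noise,
stage drift or tile misregistration, and pancreas-specific acinar
geometry. Passing tests therefore demonstrate the correctness of the
processing chain and the recoverability of schematic morphology, not
diagnostic performance on patient tissue.

## Determinism and numerics

All randomness flows from integer seeds through `numpy` generators; the
pipeline spawns per-tile child seeds from the master seed, so one config +
seed reproduces byte-identical images and provenance. Every stage is pure;
provenance records the ordered stage list, seeds and a config hash. All
rounding is half-up; quantization, LUT application and compositing operate
on exact 8-bit values. Degenerate inputs (constant rasters, empty fields,
single-level histograms) have defined outcomes noted above.

## Problem sizes used in the shipped experiments

Tests and the acceptance script run on deliberately small fields: 128–800 µm
phantoms at 0.5–1 µm/px, 100–200 px tiles, 512² mosaics for the Fourier
experiments, 10,000 pixel samples for noise statistics, and 12-crypt /
96-nucleus fields for recovery. These sizes keep the whole suite in the
tens of seconds while leaving every measured quantity's estimator error
well below the asserted tolerances.
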