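"""Acquisition models: sequential lambda-switch and simultaneous FM-SRS.

The microscope acquires 100 um x 100 um tiles (200 x 200 px by default) with
a 40 us pixel dwell and 3 accumulations. Two modalities are modelled:

lambda-switch
    The two pump wavelengths are shuttered alternately, so SRS2845 and
    SRS2930 are measured in *separate* raster passes (independent noise) and
    the nuclei contrast is obtained later by subtraction.

FM-SRS
    Both pumps are intensity-modulated at the same frequency (20 MHz) with a
    180 degree relative phase. The Stokes beam then carries
    ``g2930*SRS2930*m(t) + g2845*SRS2845*m(t + T/2)`` where ``m`` is the
    on/off square wave of the acousto-optic modulators; lock-in demodulation
    at the modulation frequency (reference in phase with the 2930 pump)
    yields the difference ``g2930*SRS2930 - g2845*SRS2845`` directly, pixel
    by pixel.

The demodulated value is computed through inner products of the synthesized
reference and modulation waveforms, and demodulated detector noise is drawn
as the exact Gaussian projection of per-sample noise onto the reference
(std ``sigma/sqrt(samples_per_pixel)`` per accumulation). This is identical
in distribution to materializing the per-pixel time series.

Accumulations are combined by arithmetic mean so the grey scale does not
depend on the accumulation count. Daily power drift is corrected by scaling
against an oil reference measured at 2930 cm^-1 (:func:`calibrate_power`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import CalibrationError, GeometryError, ParameterError, SamplingError
from .stack import CARS, FMSRS, SHG, SRS2845, SRS2930, TPEF, ChannelStack

LAMBDA_SWITCH = "lambda_switch"
FM_SRS = "fm_srs"
MODALITIES = (LAMBDA_SWITCH, FM_SRS)


@dataclass(frozen=True)
class AcquisitionParams:
    modality: str = LAMBDA_SWITCH
    tile_px: int = 200
    tile_um: float = 100.0
    dwell_us: float = 40.0
    accumulations: int = 3
    noise_sigma: float = 0.0
    gain_2845: float = 1.0
    gain_2930: float = 1.0
    modulation_freq_hz: float = 2.0e7
    samples_per_pixel: int = 6400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ParameterError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        if self.tile_px < 16:
            raise ParameterError("tile_px must be >= 16")
        if self.tile_um <= 0 or self.dwell_us <= 0:
            raise ParameterError("tile_um and dwell_us must be positive")
        if self.accumulations < 1:
            raise ParameterError("accumulations must be >= 1")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be nonnegative")
        if self.gain_2845 <= 0 or self.gain_2930 <= 0:
            raise ParameterError("gains must be strictly positive")
        if self.modulation_freq_hz <= 0:
            raise ParameterError("modulation_freq_hz must be positive")
        if self.samples_per_pixel < 8:
            raise ParameterError("samples_per_pixel must be >= 8")

    @property
    def pixel_size_um(self) -> float:
        return self.tile_um / self.tile_px


@dataclass(frozen=True)
class CalibrationRecord:
    """Oil-reference SRS power measurement at 2930 cm^-1."""

    reference_signal: float
    reference_nominal: float = 1.0

    def __post_init__(self) -> None:
        if self.reference_signal <= 0 or self.reference_nominal <= 0:
            raise CalibrationError("calibration reference values must be strictly positive")


def _check_tile(channels: ChannelStack, params: AcquisitionParams, required) -> None:
    for name in required:
        if name not in channels:
            raise GeometryError(f"input stack is missing channel {name!r}")
    if channels.shape != (params.tile_px, params.tile_px):
        raise GeometryError(
            f"tile shape {channels.shape} does not match tile_px={params.tile_px}"
        )


def _accumulated_noise(rng: np.random.Generator, sigma: float, shape, accumulations: int) -> np.ndarray:
    """Mean of `accumulations` independent Gaussian noise frames."""
    if sigma == 0:
        return np.zeros(shape)
    draws = rng.normal(0.0, sigma, size=(accumulations,) + tuple(shape))
    return draws.mean(axis=0)


def acquire_lambda_switch(channels: ChannelStack, params: AcquisitionParams) -> ChannelStack:
    """Sequential two-wavenumber acquisition.

    Each channel is ``gain * truth`` plus the mean of `accumulations`
    independent Gaussian noise frames; the two SRS passes and every detector
    get independent noise realizations.
    """
    _check_tile(channels, params, (SRS2845, SRS2930, SHG))
    rng = np.random.default_rng(params.seed)
    gains = {SRS2845: params.gain_2845, SRS2930: params.gain_2930}
    out = {}
    for name in (SRS2845, SRS2930, SHG, TPEF, CARS):
        if name not in channels:
            continue
        gain = gains.get(name, 1.0)
        out[name] = gain * channels[name] + _accumulated_noise(
            rng, params.noise_sigma, channels.shape, params.accumulations
        )
    return channels.copy_with(out, modality=LAMBDA_SWITCH)


def _modulation_waveforms(params: AcquisitionParams):
    """One dwell's worth of the AOM square waves and the lock-in reference.

    Returns (m2930, m2845, ref) of length ``samples_per_pixel``. The sampling
    must tile an integer number of modulation periods with an even number of
    samples per period, otherwise the demodulation sums are biased.
    """
    n_periods_f = params.dwell_us * 1e-6 * params.modulation_freq_hz
    n_periods = int(round(n_periods_f))
    if n_periods < 1 or abs(n_periods_f - n_periods) > 1e-9:
        raise SamplingError(
            f"dwell of {params.dwell_us} us does not span an integer number of "
            f"{params.modulation_freq_hz} Hz modulation periods"
        )
    if params.samples_per_pixel % n_periods:
        raise SamplingError(
            f"samples_per_pixel={params.samples_per_pixel} is not a multiple of "
            f"the {n_periods} modulation periods per dwell"
        )
    p = params.samples_per_pixel // n_periods
    if p < 2 or p % 2:
        raise SamplingError(
            f"{p} samples per modulation period; need an even count >= 2 for a "
            "50% duty square wave"
        )
    period = np.concatenate([np.ones(p // 2), np.zeros(p // 2)])
    m2930 = np.tile(period, n_periods)
    m2845 = np.roll(m2930, p // 2)  # 180 degree AOM phase shift
    ref = 2.0 * m2930 - 1.0  # zero-mean lock-in reference, in phase with 2930
    return m2930, m2845, ref


def acquire_fm_srs(channels: ChannelStack, params: AcquisitionParams) -> ChannelStack:
    """Simultaneous FM-SRS acquisition.

    Returns a stack with the demodulated ``FMSRS`` channel (proportional to
    ``gain_2930*SRS2930 - gain_2845*SRS2845``) plus SHG and any TPEF/CARS
    channels acquired in the same scan (independent per-detector noise).
    """
    _check_tile(channels, params, (SRS2845, SRS2930, SHG))
    m2930, m2845, ref = _modulation_waveforms(params)
    n = params.samples_per_pixel
    w2930 = float(np.mean(ref * m2930))  # reference/modulation overlap (0.5)
    w2845 = float(np.mean(ref * m2845))  # (-0.5)

    rng = np.random.default_rng(params.seed)
    raw = (
        params.gain_2930 * channels[SRS2930] * w2930
        + params.gain_2845 * channels[SRS2845] * w2845
    )
    if params.noise_sigma > 0:
        # projection of per-sample detector noise onto the unit-power reference
        demod_sigma = params.noise_sigma / np.sqrt(n)
        raw = raw + _accumulated_noise(rng, demod_sigma, channels.shape, params.accumulations)
    fmsrs = raw / w2930  # normalize the lock-in output back to signal units

    out = {FMSRS: fmsrs}
    for name in (SHG, TPEF, CARS):
        if name in channels:
            out[name] = channels[name] + _accumulated_noise(
                rng, params.noise_sigma, channels.shape, params.accumulations
            )
    return channels.copy_with(out, modality=FM_SRS)


def acquire(channels: ChannelStack, params: AcquisitionParams) -> ChannelStack:
    """Dispatch on ``params.modality``."""
    if params.modality == LAMBDA_SWITCH:
        return acquire_lambda_switch(channels, params)
    return acquire_fm_srs(channels, params)


def calibrate_power(channel: np.ndarray, cal: CalibrationRecord) -> np.ndarray:
    """Rescale a raster by the oil-reference power ratio."""
    if cal.reference_signal <= 0 or cal.reference_nominal <= 0:
        raise CalibrationError("calibration reference values must be strictly positive")
    return np.asarray(channel, dtype=np.float64) * (cal.reference_nominal / cal.reference_signal)
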