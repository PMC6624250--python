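"""Acquisition models: noiseless limits, noise statistics, FM-SRS demodulation."""

from dataclasses import replace

import numpy as np
import pytest

from srh import AcquisitionParams, CalibrationRecord, calibrate_power
from srh.acquisition import acquire_fm_srs, acquire_lambda_switch, _modulation_waveforms
from srh.errors import CalibrationError, GeometryError, ParameterError, SamplingError
from srh.stack import CARS, FMSRS, SHG, SRS2845, SRS2930, TPEF, ChannelStack


def _stack(rng, tile_px=32, include_aux=False):
    channels = {
        SRS2845: rng.uniform(0, 1, (tile_px, tile_px)),
        SRS2930: rng.uniform(0, 2, (tile_px, tile_px)),
        SHG: rng.uniform(0, 1, (tile_px, tile_px)),
    }
    if include_aux:
        channels[TPEF] = rng.uniform(0, 1, (tile_px, tile_px))
        channels[CARS] = rng.uniform(0, 1, (tile_px, tile_px))
    return ChannelStack(channels=channels, pixel_size_um=0.5)


@pytest.fixture
def params32():
    return AcquisitionParams(tile_px=32, noise_sigma=0.0, seed=9)


class TestLambdaSwitch:
    def test_noiseless_output_is_gain_times_truth(self, rng, params32):
        stack = _stack(rng)
        p = replace(params32, gain_2845=1.5, gain_2930=2.5)
        out = acquire_lambda_switch(stack, p)
        np.testing.assert_allclose(out[SRS2845], 1.5 * stack[SRS2845])
        np.testing.assert_allclose(out[SRS2930], 2.5 * stack[SRS2930])
        np.testing.assert_allclose(out[SHG], stack[SHG])

    def test_zero_truth_zero_noise_gives_zero(self, params32):
        zero = ChannelStack(
            {n: np.zeros((32, 32)) for n in (SRS2845, SRS2930, SHG)}, pixel_size_um=0.5
        )
        out = acquire_lambda_switch(zero, params32)
        for n in (SRS2845, SRS2930, SHG):
            assert not out[n].any()

    def test_accumulation_reduces_noise_std_as_sqrt_n(self, params32):
        """With 4 accumulations the per-pixel std is sigma/2 (10,000 samples)."""
        sigma = 1.0
        p = replace(params32, tile_px=100, noise_sigma=sigma, accumulations=4)
        zero = ChannelStack(
            {n: np.zeros((100, 100)) for n in (SRS2845, SRS2930, SHG)}, pixel_size_um=1.0
        )
        out = acquire_lambda_switch(zero, p)
        measured = out[SHG].std()
        assert abs(measured - sigma / 2.0) <= 0.05 * (sigma / 2.0)

    def test_sequential_passes_get_independent_noise(self, params32):
        p = replace(params32, noise_sigma=0.5)
        zero = ChannelStack(
            {n: np.zeros((32, 32)) for n in (SRS2845, SRS2930, SHG)}, pixel_size_um=1.0
        )
        out = acquire_lambda_switch(zero, p)
        assert not np.array_equal(out[SRS2845], out[SRS2930])

    def test_shape_mismatch_raises(self, rng, params32):
        stack = _stack(rng, tile_px=16)
        with pytest.raises(GeometryError):
            acquire_lambda_switch(stack, params32)

    def test_deterministic_per_seed(self, rng, params32):
        stack = _stack(rng)
        p = replace(params32, noise_sigma=0.3)
        a = acquire_lambda_switch(stack, p)
        b = acquire_lambda_switch(stack, p)
        assert all(np.array_equal(a[n], b[n]) for n in a.names)


class TestFMSRS:
    def test_equal_signals_cancel(self, rng, params32):
        same = rng.uniform(0, 3, (32, 32))
        stack = ChannelStack(
            {SRS2845: same, SRS2930: same.copy(), SHG: np.zeros((32, 32))}, pixel_size_um=1.0
        )
        out = acquire_fm_srs(stack, params32)
        assert np.max(np.abs(out[FMSRS])) < 1e-9 * same.max()

    def test_noiseless_fm_equals_lambda_switch_subtraction(self, rng, params32):
        """The lock-in directly provides the SRS signal difference."""
        stack = _stack(rng)
        fm = acquire_fm_srs(stack, params32)
        ls = acquire_lambda_switch(stack, params32)
        diff = ls[SRS2930] - ls[SRS2845]
        scale = np.max(np.abs(diff))
        assert np.max(np.abs(fm[FMSRS] - diff)) <= 1e-6 * scale

    def test_single_pixel_against_timeseries_oracle(self, params32):
        """Full numerical lock-in (multiply by reference, average) agrees."""
        truth = 2.7
        stack = ChannelStack(
            {
                SRS2845: np.zeros((32, 32)),
                SRS2930: np.zeros((32, 32)),
                SHG: np.zeros((32, 32)),
            },
            pixel_size_um=1.0,
        )
        stack.channels[SRS2930][4, 5] = truth
        gain = 1.3
        p = replace(params32, gain_2930=gain)
        out = acquire_fm_srs(stack, p)

        # oracle: synthesize the full dwell time series for that pixel and
        # demodulate it numerically
        n_periods = int(round(p.dwell_us * 1e-6 * p.modulation_freq_hz))
        spp = p.samples_per_pixel
        per = spp // n_periods
        m2930 = np.tile(np.r_[np.ones(per // 2), np.zeros(per // 2)], n_periods)
        ref = 2.0 * m2930 - 1.0
        series = gain * truth * m2930  # SRS2845 contribution is zero
        demod = np.mean(ref * series) / np.mean(ref * m2930)
        assert out[FMSRS][4, 5] == pytest.approx(demod, rel=1e-12)
        assert demod == pytest.approx(gain * truth, rel=1e-12)

    def test_aux_channels_pass_through_with_own_noise(self, rng, params32):
        stack = _stack(rng, include_aux=True)
        out = acquire_fm_srs(stack, params32)
        np.testing.assert_allclose(out[TPEF], stack[TPEF])
        np.testing.assert_allclose(out[CARS], stack[CARS])
        assert SHG in out

    def test_incommensurate_sampling_raises(self, params32):
        with pytest.raises(SamplingError):
            acquire_fm_srs(
                _stack(np.random.default_rng(0)),
                replace(params32, samples_per_pixel=6401),
            )
        with pytest.raises(SamplingError):
            # 1 sample per period cannot represent a 50% duty square wave
            acquire_fm_srs(
                _stack(np.random.default_rng(0)),
                replace(params32, samples_per_pixel=800),
            )

    def test_waveforms_are_balanced(self, params32):
        m2930, m2845, ref = _modulation_waveforms(params32)
        assert np.mean(ref) == 0.0
        assert np.mean(ref * m2930) == pytest.approx(0.5)
        assert np.mean(ref * m2845) == pytest.approx(-0.5)


class TestCalibration:
    def test_identity_scaling(self, rng):
        arr = rng.uniform(0, 5, (8, 8))
        out = calibrate_power(arr, CalibrationRecord(reference_signal=2.0, reference_nominal=2.0))
        np.testing.assert_array_equal(out, arr)

    def test_double_reference_halves_values(self, rng):
        arr = rng.uniform(0, 5, (8, 8))
        out = calibrate_power(arr, CalibrationRecord(reference_signal=2.0, reference_nominal=1.0))
        np.testing.assert_allclose(out, arr / 2.0)

    def test_arbitrary_ratio_elementwise_oracle(self, rng):
        arr = rng.uniform(0, 5, (16, 16))
        r = 3.7
        cal = CalibrationRecord(reference_signal=r, reference_nominal=1.0)
        np.testing.assert_allclose(calibrate_power(arr, cal), arr * (1.0 / r))

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(CalibrationError):
            CalibrationRecord(reference_signal=0.0)
        with pytest.raises(CalibrationError):
            CalibrationRecord(reference_signal=1.0, reference_nominal=-2.0)

    def test_calibration_commutes_with_noiseless_acquisition(self, rng):
        stack = _stack(rng)
        p = AcquisitionParams(tile_px=32, noise_sigma=0.0)
        cal = CalibrationRecord(reference_signal=1.6, reference_nominal=1.0)
        a = acquire_lambda_switch(stack, p)
        cal_after = {n: calibrate_power(a[n], cal) for n in a.names}
        pre = stack.copy_with({n: calibrate_power(stack[n], cal) for n in stack.names})
        cal_before = acquire_lambda_switch(pre, p)
        for n in cal_after:
            np.testing.assert_allclose(cal_after[n], cal_before[n], rtol=1e-12)


def test_invalid_acquisition_params():
    with pytest.raises(ParameterError):
        AcquisitionParams(tile_px=8)
    with pytest.raises(ParameterError):
        AcquisitionParams(accumulations=0)
    with pytest.raises(ParameterError):
        AcquisitionParams(gain_2845=0.0)
    with pytest.raises(ParameterError):
        AcquisitionParams(modality="spiral")
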