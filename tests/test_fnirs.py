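"""fNIRS chain: motion correction, band-pass, Beer-Lambert, block averaging."""

import numpy as np
import pytest

from cifes.fnirs import (ChannelGeometry, OpticalDensityPair, bandpass,
                         block_average, mbll, mbll_forward,
                         motion_correct_spline, task_variance)
from cifes.io import Event, EventList, Trace

FS = 10.0


def _od(values, fs=FS):
    return Trace("od", fs, np.asarray(values, dtype=float), units="OD")


class TestMotionCorrection:
    def test_clean_trace_returned_unchanged(self, rng):
        tr = _od(0.001 * rng.standard_normal(600))
        out = motion_correct_spline(tr)
        np.testing.assert_array_equal(out.values, tr.values)

    def test_step_artifact_suppressed(self, rng):
        base = 0.001 * rng.standard_normal(600)
        x = base.copy()
        x[200:220] += 0.5  # 2 s boxcar artifact
        out = motion_correct_spline(_od(x))
        resid = np.abs(out.values[200:220] - base[200:220]).max()
        assert resid < 0.2 * 0.5  # >= 80% reduction

    def test_samples_outside_segments_untouched(self, rng):
        base = 0.001 * rng.standard_normal(600)
        x = base.copy()
        x[300:320] += 0.5
        out = motion_correct_spline(_od(x))
        np.testing.assert_array_equal(out.values[:250], x[:250])
        np.testing.assert_array_equal(out.values[370:], x[370:])

    def test_idempotent_on_corrected_trace(self, rng):
        x = 0.001 * rng.standard_normal(600)
        x[200:220] += 0.5
        once = motion_correct_spline(_od(x))
        twice = motion_correct_spline(once)
        np.testing.assert_array_equal(twice.values, once.values)


class TestBandpass:
    def test_dc_rejected(self):
        out = bandpass(_od(np.full(4000, 0.7)))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-6)

    def test_midband_sinusoid_preserved(self):
        t = np.arange(12000) / FS
        out = bandpass(_od(np.sin(2 * np.pi * 0.05 * t)))
        amp = np.max(np.abs(out.values[2000:-2000]))
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_cardiac_band_attenuated(self):
        t = np.arange(12000) / FS
        out = bandpass(_od(np.sin(2 * np.pi * 1.0 * t)))
        amp = np.max(np.abs(out.values[2000:-2000]))
        assert amp < 0.1  # >= 90% attenuation

    def test_nyquist_guard(self):
        with pytest.raises(ValueError):
            bandpass(_od(np.zeros(100), fs=0.3))


class TestMBLL:
    def test_zero_od_zero_concentration(self):
        pair = OpticalDensityPair(_od(np.zeros(50)), _od(np.zeros(50)))
        hemo = mbll(pair)
        assert np.all(hemo.hbo.values == 0.0)
        assert np.all(hemo.hbt.values == 0.0)

    def test_forward_inverse_round_trip(self):
        """dOD synthesized from (dHbO, dHbR) = (1.0, -0.3) umol/L inverts to
        the same concentrations to numerical precision."""
        n = 200
        pair = mbll_forward(np.full(n, 1.0), np.full(n, -0.3))
        hemo = mbll(pair)
        np.testing.assert_allclose(hemo.hbo.values, 1.0, rtol=1e-10)
        np.testing.assert_allclose(hemo.hbr.values, -0.3, rtol=1e-10)

    def test_hbt_is_sum_on_random_inputs(self, rng):
        pair = OpticalDensityPair(_od(0.01 * rng.standard_normal(300)),
                                  _od(0.01 * rng.standard_normal(300)))
        hemo = mbll(pair)
        np.testing.assert_allclose(hemo.hbt.values,
                                   hemo.hbo.values + hemo.hbr.values, atol=1e-12)

    def test_singular_extinction_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            ChannelGeometry(extinction=np.array([[1.0, 2.0], [2.0, 4.0]]))

    def test_mismatched_wavelength_traces_rejected(self):
        with pytest.raises(ValueError):
            OpticalDensityPair(_od(np.zeros(10)), _od(np.zeros(11)))


class TestBlockAverage:
    def test_single_onset_returns_baselined_window(self):
        x = np.arange(100, dtype=float)
        tr = Trace("h", FS, x, units="umol/L")
        out = block_average(tr, EventList([Event(2.0, 2.0)]), 3.0)
        np.testing.assert_allclose(out.values, x[20:50] - x[20])

    def test_two_identical_blocks_average_to_either(self):
        block = np.sin(np.linspace(0, np.pi, 50))
        x = np.concatenate([block, block])
        tr = Trace("h", FS, x, units="umol/L")
        out = block_average(tr, EventList([Event(0.0, 0.0), Event(5.0, 5.0)]), 5.0)
        np.testing.assert_allclose(out.values, block - block[0], atol=1e-12)

    def test_noise_reduction_scales_as_sqrt_n(self, rng):
        """25 noisy repeats of a fixed response: residual noise SD drops by
        about a factor 5."""
        n_blocks, win = 25, 20.0
        resp = np.sin(np.linspace(0, np.pi, int(win * FS)))
        resp -= resp[0]
        noise_sd = 0.5
        x = np.concatenate([resp + rng.normal(0, noise_sd, resp.size)
                            for _ in range(n_blocks)])
        tr = Trace("h", FS, x, units="umol/L")
        onsets = EventList([Event(i * win, i * win) for i in range(n_blocks)])
        out = block_average(tr, onsets, win)
        resid_sd = np.std(out.values - resp)
        assert noise_sd / resid_sd == pytest.approx(5.0, rel=0.45)

    def test_out_of_range_onset_rejected(self):
        tr = Trace("h", FS, np.zeros(50), units="umol/L")
        with pytest.raises(ValueError, match="9"):
            block_average(tr, EventList([Event(9.0, 9.0)]), 45.0)


class TestTaskVariance:
    def test_constant_trace_zero_variance(self):
        tr = Trace("h", FS, np.full(500, 0.3), units="umol/L")
        assert task_variance(tr) == pytest.approx(0.0, abs=1e-12)

    def test_sinusoid_variance_A2_over_2(self):
        A, f = 0.4, 0.2
        t = np.arange(int(45.0 * FS)) / FS  # whole number of 5 s periods
        tr = Trace("h", FS, A * np.sin(2 * np.pi * f * t), units="umol/L")
        assert task_variance(tr, 45.0) == pytest.approx(A * A / 2, rel=0.02)

    def test_offset_invariance(self, rng):
        x = rng.normal(0, 0.1, 500)
        a = task_variance(Trace("h", FS, x, units="umol/L"))
        b = task_variance(Trace("h", FS, x + 5.0, units="umol/L"))
        assert a == pytest.approx(b, rel=1e-9)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            task_variance(Trace("h", FS, np.zeros(10), units="umol/L"), 45.0)


class TestFullChain:
    def _hrf(self, t, onset):
        tt = t - onset
        m = (tt > 0) & (tt < 25)
        out = np.zeros_like(t)
        out[m] = (tt[m] / 6.0) ** 2 * np.exp(-(tt[m] - 6.0) / 2.0)
        return out

    def test_round_trip_recovers_response_peak(self, rng):
        """Synthetic hemodynamics + cardiac/respiratory sinusoids + spike
        artifacts, forward Beer-Lambert, full pipeline: block-averaged HbO
        peak recovered within 10%."""
        n_blocks, block = 20, 40.0
        n = int(n_blocks * block * FS)
        t = np.arange(n) / FS
        onsets = np.arange(n_blocks) * block + 2.0
        resp = sum(self._hrf(t, o) for o in onsets)
        resp /= resp.max()
        hbo = resp + 0.15 * np.sin(2 * np.pi * 1.0 * t) \
            + 0.1 * np.sin(2 * np.pi * 0.3 * t)
        hbr = -0.3 * resp + 0.05 * np.sin(2 * np.pi * 1.0 * t)
        spikes = np.zeros(n)
        for i in rng.integers(100, n - 100, 6):
            spikes[i:i + 3] += 2.0
        pair = mbll_forward(hbo + spikes, hbr, sampling_rate=FS)
        od1 = bandpass(motion_correct_spline(pair.od_lambda1))
        od2 = bandpass(motion_correct_spline(pair.od_lambda2))
        hemo = mbll(OpticalDensityPair(od1, od2))
        ev = EventList([Event(o, o + 30.0) for o in onsets])
        avg = block_average(hemo.hbo, ev, 30.0)
        assert avg.values.max() == pytest.approx(1.0, abs=0.1)

    def test_pipeline_homogeneity_without_artifacts(self):
        t = np.arange(4000) / FS
        resp = self._hrf(t, 5.0) + self._hrf(t, 100.0)
        for scale in (1.0, 3.0):
            pair = mbll_forward(scale * resp, -0.3 * scale * resp,
                                sampling_rate=FS)
            out = mbll(OpticalDensityPair(bandpass(pair.od_lambda1),
                                          bandpass(pair.od_lambda2)))
            if scale == 1.0:
                ref = out.hbo.values
            else:
                np.testing.assert_allclose(out.hbo.values, scale * ref,
                                           rtol=1e-8, atol=1e-10)
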