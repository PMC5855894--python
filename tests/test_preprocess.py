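"""Filtering, downsampling, epoching and blink segmentation contracts."""

import numpy as np
import pytest

import neuroauth as na
from neuroauth.synthgen import CHANNEL_LABELS, blink_template


def _sine_recording(freq, rate=600.0, dur=10.0, amp=10.0):
    t = np.arange(int(dur * rate)) / rate
    x = amp * np.sin(2 * np.pi * freq * t)
    return na.MultichannelRecording(np.tile(x, (16, 1)), rate,
                                    list(CHANNEL_LABELS))


def _rms(x):
    return np.sqrt(np.mean(x ** 2))


class TestLowpass:
    def test_dc_gain_unity(self):
        rec = na.MultichannelRecording(np.full((16, 3000), 5.0), 600.0,
                                       list(CHANNEL_LABELS))
        out = na.lowpass_eeg(rec)
        # interior samples away from filtfilt edge transients
        np.testing.assert_allclose(out.samples[:, 500:-500], 5.0, rtol=0.02)

    def test_stopband_sine_removed(self):
        out = na.lowpass_eeg(_sine_recording(60.0))
        x = out.samples[0, 600:-600]
        assert _rms(x) < 0.01 * _rms(_sine_recording(60.0).samples[0])

    def test_passband_sine_preserved(self):
        inp = _sine_recording(10.0)
        out = na.lowpass_eeg(inp)
        mid = slice(600, -600)
        ratio = _rms(out.samples[0, mid]) / _rms(inp.samples[0, mid])
        # 0.5 dB design ripple is applied twice by the zero-phase pass
        assert 0.88 < ratio < 1.01

    def test_rate_too_low_names_nyquist(self):
        rec = na.MultichannelRecording(np.zeros((16, 500)), 90.0,
                                       list(CHANNEL_LABELS))
        with pytest.raises(ValueError, match="Nyquist"):
            na.lowpass_eeg(rec)


class TestBandpassBlink:
    def test_dc_rejected(self):
        rec = na.SingleChannelRecording(np.full(6000, 50.0), 600.0)
        out = na.bandpass_blink(rec)
        assert np.abs(out.samples[1000:-1000]).max() < 0.5

    def test_10hz_passes_01hz_attenuated(self):
        t = np.arange(30000) / 600.0
        for freq, passes in ((10.0, True), (0.1, False)):
            rec = na.SingleChannelRecording(100 * np.sin(2 * np.pi * freq * t),
                                            600.0)
            out = na.bandpass_blink(rec)
            ratio = _rms(out.samples[3000:-3000]) / _rms(
                rec.samples[3000:-3000])
            if passes:
                assert ratio > 0.9
            else:
                assert ratio < 0.1


class TestDownsample:
    def test_four_sample_mean(self):
        rec = na.SingleChannelRecording(np.array([1.0, 2.0, 3.0, 4.0]),
                                        2400.0)
        out = na.downsample_by_averaging(rec, 4)
        np.testing.assert_array_equal(out.samples, [2.5])
        assert out.rate == 600.0

    def test_2400_to_600(self):
        rec = na.MultichannelRecording(np.random.default_rng(0).normal(
            size=(16, 2400)), 2400.0, list(CHANNEL_LABELS))
        out = na.downsample_by_averaging(rec, 4)
        assert out.rate == 600.0
        assert out.samples.shape == (16, 600)

    def test_constant_preserved(self):
        rec = na.SingleChannelRecording(np.full(100, 7.0), 2400.0)
        out = na.downsample_by_averaging(rec, 4)
        assert np.all(out.samples == 7.0)

    def test_mean_preserved(self):
        x = np.random.default_rng(1).normal(size=1200)
        rec = na.SingleChannelRecording(x, 2400.0)
        out = na.downsample_by_averaging(rec, 4)
        assert np.isclose(out.samples.mean(), x.mean())

    def test_bad_factor(self):
        rec = na.SingleChannelRecording(np.zeros(8), 2400.0)
        with pytest.raises(ValueError):
            na.downsample_by_averaging(rec, 0)


class TestEpoching:
    def test_constant_channel_zeroed_by_baseline(self):
        rec = na.MultichannelRecording(np.full((16, 3000), 7.0), 600.0,
                                       list(CHANNEL_LABELS))
        ev = na.EventList(np.array([500, 1500]), ["self", "nonself"])
        ep = na.epoch_and_baseline(rec, ev)
        np.testing.assert_allclose(ep.data, 0.0, atol=1e-9)

    def test_shape_arithmetic(self, epochs):
        # 1.2 s at 600 Hz = 720 samples, 120 of them pre-stimulus
        assert epochs.data.shape == (200, 16, 720)
        assert epochs.baseline_samples == 120
        assert epochs.post_stimulus.shape[-1] == 600
        assert epochs.N1 + epochs.N2 == 200

    def test_baseline_mean_zero(self, epochs):
        base = epochs.data[:, :, :120].mean(axis=2)
        np.testing.assert_allclose(base, 0.0, atol=1e-9)

    def test_baseline_correction_idempotent(self, session_600):
        rec, events = session_600
        ep1 = na.epoch_and_baseline(rec, events)
        # re-epoching the already-corrected data changes nothing:
        # subtracting an (already zero) baseline mean is a no-op
        again = ep1.data - ep1.data[:, :, :120].mean(axis=2, keepdims=True)
        np.testing.assert_allclose(again, ep1.data, atol=1e-12)

    def test_out_of_bounds_names_event(self):
        rec = na.MultichannelRecording(np.zeros((16, 1000)), 600.0,
                                       list(CHANNEL_LABELS))
        ev = na.EventList(np.array([0]), ["self"])
        with pytest.raises(ValueError, match="event 0"):
            na.epoch_and_baseline(rec, ev)


class TestDetectBlinks:
    def test_flat_trace_empty(self):
        rec = na.SingleChannelRecording(np.zeros(5000), 600.0)
        assert na.detect_blinks(rec) == []

    def test_single_pulse_boundaries_match_analytic(self, profile):
        rate = 600.0
        rec = na.gen_blink_session(profile, 1, noise_sd=0.0, seed=3,
                                   rate=rate)
        onset = int(rec.blink_onsets[0])
        tmpl = blink_template(profile, rate)
        n_pos = int(round(profile.blink_rise_ms / 1000 * rate)) + \
            int(round(profile.blink_fall_ms / 1000 * rate))
        blinks = na.detect_blinks(rec)
        assert len(blinks) == 1
        b = blinks[0]
        assert abs(b.start_idx - onset) <= 1
        assert abs(b.end_idx - (onset + tmpl.size - 1)) <= 1
        # positive peak at end of rise segment, negative mid-undershoot
        rise = int(round(profile.blink_rise_ms / 1000 * rate))
        assert abs(b.pos_peak_idx - (onset + rise)) <= 1
        und = int(round(profile.blink_undershoot_ms / 1000 * rate))
        assert abs(b.neg_peak_idx - (onset + n_pos + und // 2)) <= 1

    def test_positive_only_pulse_rejected(self):
        x = np.zeros(2000)
        x[900:1100] = 120 * np.sin(np.pi * np.arange(200) / 200)
        rec = na.SingleChannelRecording(x, 600.0)
        assert na.detect_blinks(rec) == []

    def test_recovers_generated_count_zero_noise(self, profile):
        rec = na.gen_blink_session(profile, 7, noise_sd=0.0, seed=11,
                                   rate=600.0)
        blinks = na.detect_blinks(rec)
        assert len(blinks) == 7
        for b, onset in zip(blinks, rec.blink_onsets):
            assert abs(b.start_idx - onset) <= 1

    def test_largest_positive_peak_kept(self):
        # two supra-threshold positive peaks before one negative peak
        x = np.zeros(3000)
        x[500:700] = 110 * np.sin(np.pi * np.arange(200) / 200)
        x[800:1000] = 150 * np.sin(np.pi * np.arange(200) / 200)
        x[1100:1300] = -80 * np.sin(np.pi * np.arange(200) / 200)
        rec = na.SingleChannelRecording(x, 600.0)
        blinks = na.detect_blinks(rec)
        assert len(blinks) == 1
        assert np.isclose(blinks[0].raw_pos_peak, 150.0, atol=1.0)


class TestNormalizeBlinks:
    def _blink(self, pos, neg, rate=600.0):
        x = np.zeros(400)
        x[:200] = pos * np.sin(np.pi * np.arange(200) / 200)
        x[200:] = neg * np.sin(np.pi * np.arange(200) / 200)
        return na.BlinkWaveform(samples=x, rate=rate, start_idx=0,
                                end_idx=399, pos_peak_idx=100,
                                neg_peak_idx=300, raw_pos_peak=pos,
                                raw_neg_peak=neg)

    def test_single_blink_division(self):
        out = na.normalize_blinks([self._blink(200.0, -80.0)])
        assert np.isclose(out[0].samples.max(), 1.0)
        assert np.isclose(out[0].samples.min(), -0.4)

    def test_global_maximum_over_list(self):
        out = na.normalize_blinks([self._blink(100.0, -60.0),
                                   self._blink(200.0, -60.0)])
        assert np.isclose(out[1].samples.max(), 1.0)
        assert np.isclose(out[0].samples.max(), 0.5)
        peak = max(np.abs(b.samples).max() for b in out)
        assert peak == 1.0

    def test_idempotent(self):
        once = na.normalize_blinks([self._blink(150.0, -70.0)])
        twice = na.normalize_blinks(once)
        np.testing.assert_array_equal(once[0].samples, twice[0].samples)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            na.normalize_blinks([])
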