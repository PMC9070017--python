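"""Filtering, resampling, pooling and epoching contracts."""

import numpy as np
import pytest

from rsvp_alpha.config import CHANNELS, POOL
from rsvp_alpha.preprocess import (bandpass_notch, epoch, pool_channels,
                                   resample)
from rsvp_alpha.sim import Marker, RawRecording


def _tone_recording(freq, fs=300.0, dur_s=10.0, amp=1.0):
    t = np.arange(int(dur_s * fs)) / fs
    data = np.tile(amp * np.sin(2 * np.pi * freq * t), (len(CHANNELS), 1))
    return RawRecording(data=data, fs=fs, channels=CHANNELS, events=[])


def _rms(x):
    return np.sqrt(np.mean(x ** 2))


class TestFilter:
    def test_passband_tone_preserved(self):
        rec = _tone_recording(10.0)
        out = bandpass_notch(rec)
        mid = slice(600, 2400)    # avoid filter edge transients
        assert _rms(out.data[0, mid]) > 0.95 * _rms(rec.data[0, mid])

    def test_notch_removes_line_frequency(self):
        rec = _tone_recording(60.0)
        out = bandpass_notch(rec)
        mid = slice(600, 2400)
        assert _rms(out.data[0, mid]) < 0.1 * _rms(rec.data[0, mid])

    def test_stopband_tone_removed(self):
        rec = _tone_recording(80.0)
        out = bandpass_notch(rec)
        mid = slice(600, 2400)    # avoid filter edge transients
        assert _rms(out.data[0, mid]) < 0.05 * _rms(rec.data[0, mid])

    def test_zeros_stay_zeros(self):
        rec = _tone_recording(10.0, amp=0.0)
        out = bandpass_notch(rec)
        assert np.allclose(out.data, 0.0)

    def test_invalid_band_edges(self):
        rec = _tone_recording(10.0)
        with pytest.raises(ValueError):
            bandpass_notch(rec, low_hz=1.0, high_hz=200.0)
        with pytest.raises(ValueError):
            bandpass_notch(rec, low_hz=50.0, high_hz=45.0)

    def test_pooling_commutes_with_filtering(self):
        rng = np.random.default_rng(0)
        rec = RawRecording(data=rng.standard_normal((len(CHANNELS), 3000)),
                           fs=300.0, channels=CHANNELS, events=[])
        a = pool_channels(bandpass_notch(rec))
        b = bandpass_notch(pool_channels(rec))
        np.testing.assert_allclose(a.data[-1], b.data[-1], atol=1e-9)


class TestResample:
    def test_halving_rate_halves_samples_and_rescales_events(self):
        rec = _tone_recording(10.0, dur_s=10.0)
        rec.events.append(Marker(sample=600, label="target"))
        out = resample(rec, 150.0)
        assert out.fs == 150.0
        assert out.data.shape[1] == 1500
        assert out.events[0].sample == 300

    def test_identity_when_rate_unchanged(self):
        rec = _tone_recording(10.0)
        out = resample(rec, 300.0)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            resample(_tone_recording(10.0), 600.0)


class TestPool:
    def test_pool_is_arithmetic_mean(self):
        data = np.zeros((len(CHANNELS), 10))
        for i, v in zip([2, 6, 4, 5], [1.0, 2.0, 3.0, 4.0]):  # Pz,Oz,PO7,PO8
            data[i] = v
        rec = RawRecording(data=data, fs=300.0, channels=CHANNELS, events=[])
        out = pool_channels(rec)
        assert out.channels[-1] == POOL
        np.testing.assert_allclose(out.data[-1], 2.5)

    def test_single_channel_pool_equals_channel(self):
        rng = np.random.default_rng(1)
        rec = RawRecording(data=rng.standard_normal((len(CHANNELS), 50)),
                           fs=300.0, channels=CHANNELS, events=[])
        out = pool_channels(rec, subset=("Pz",))
        np.testing.assert_array_equal(out.data[-1],
                                      rec.data[rec.channel_index("Pz")])

    def test_missing_channel_raises(self):
        rec = _tone_recording(10.0)
        with pytest.raises(KeyError):
            pool_channels(rec, subset=("Cz",))


class TestEpoch:
    def _recording_with_events(self, n_events=10, fs=150.0, dur_s=30.0):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((len(CHANNELS), int(dur_s * fs)))
        events = [Marker(sample=int((3 + i * 2) * fs),
                         label="target" if i % 10 == 0 else "nontarget")
                  for i in range(n_events)]
        return RawRecording(data=data, fs=fs, channels=CHANNELS,
                            events=events)

    @pytest.mark.parametrize("window,expected_samples",
                             [((-1250.0, 1250.0), 375),
                              ((-200.0, 800.0), 150)])
    def test_sample_counts(self, window, expected_samples):
        rec = self._recording_with_events()
        eps = epoch(rec, window)
        assert eps.n_epochs == 10
        assert eps.n_samples == expected_samples

    def test_epochs_are_slices_of_the_recording(self):
        rec = self._recording_with_events()
        eps = epoch(rec, (-200.0, 800.0))
        ev = rec.events[0]
        lo = ev.sample + int(round(-200 / 1000 * rec.fs))
        np.testing.assert_array_equal(eps.data[0],
                                      rec.data[:, lo:lo + eps.n_samples])

    def test_out_of_bounds_epochs_dropped_and_counted(self):
        rec = self._recording_with_events(dur_s=30.0)
        rec.events.append(Marker(sample=rec.n_samples - 5, label="target"))
        eps = epoch(rec, (-1250.0, 1250.0))
        assert eps.n_epochs + len(eps.dropped) == len(rec.events)
        assert len(eps.dropped) == 1

    def test_recording_shorter_than_window(self):
        rec = RawRecording(data=np.zeros((len(CHANNELS), 100)), fs=150.0,
                           channels=CHANNELS,
                           events=[Marker(sample=50, label="target")])
        eps = epoch(rec, (-1250.0, 1250.0))
        assert eps.n_epochs == 0
        assert eps.dropped == [0]

    def test_onset_maps_to_time_zero_sample(self):
        rec = self._recording_with_events()
        eps = epoch(rec, (-200.0, 800.0))
        times = eps.times_ms()
        k = np.argmin(np.abs(times))
        assert times[k] == 0.0
        ev = rec.events[0]
        np.testing.assert_array_equal(eps.data[0, :, k],
                                      rec.data[:, ev.sample])
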