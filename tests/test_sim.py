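"""Schedule bookkeeping and ground-truth signal content of the
synthetic calibration generator."""

import numpy as np
import pytest
from scipy.signal import hilbert

from rsvp_alpha.config import ALPHABET
from rsvp_alpha.sim import (ARTIFACT_KINDS, TARGET, SimParams,
                            inject_artifacts, make_schedule,
                            synthesize_recording)


class TestSchedule:
    @pytest.mark.parametrize("rate,trials,expected_soa",
                             [(1.0, 100, 1000.0), (4.0, 100, 250.0)])
    def test_counts_and_spacing(self, rate, trials, expected_soa):
        s = make_schedule(rate, trials, 10, seed=3)
        assert len(s.events) == trials * 10
        assert s.n_targets == trials
        assert s.n_nontargets == trials * 9
        onsets = s.onsets_ms()
        assert np.all(np.diff(onsets) > 0)
        # consecutive onsets within a sequence differ by exactly the SOA
        for trial in range(trials):
            tr = sorted(e.onset_ms for e in s.events if e.trial == trial)
            assert np.allclose(np.diff(tr), expected_soa)

    def test_one_target_per_sequence_with_matching_letter(self):
        s = make_schedule(1.0, 50, 10, seed=9)
        for trial in range(50):
            ev = [e for e in s.events if e.trial == trial]
            targets = [e for e in ev if e.label == TARGET]
            assert len(targets) == 1
            # the target letter appears exactly once in the sequence
            letters = [e.letter for e in ev]
            assert letters.count(targets[0].letter) == 1
            assert all(l in ALPHABET for l in letters)

    def test_target_positions_cover_the_sequence(self):
        s = make_schedule(4.0, 200, 10, seed=1)
        positions = {e.position for e in s.events if e.label == TARGET}
        assert positions == set(range(10))

    def test_empty_and_invalid(self):
        assert make_schedule(1.0, 0, 10, seed=0).events == []
        with pytest.raises(ValueError):
            make_schedule(0.0, 10, 10, seed=0)
        with pytest.raises(ValueError):
            make_schedule(1.0, 10, 0, seed=0)


class TestScheduleProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(rate=st.sampled_from([1.0, 2.0, 4.0]),
           n_trials=st.integers(0, 12),
           seq_len=st.integers(1, 12),
           seed=st.integers(0, 2 ** 20))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_schedule_invariants(self, rate, n_trials, seq_len, seed):
        s = make_schedule(rate, n_trials, seq_len, seed=seed)
        assert len(s.events) == n_trials * seq_len
        assert s.n_targets == n_trials
        assert s.n_nontargets == n_trials * (seq_len - 1)
        onsets = s.onsets_ms()
        assert np.all(np.diff(onsets) > 0)
        for trial in range(n_trials):
            tr = [e.onset_ms for e in s.events if e.trial == trial]
            assert np.allclose(np.diff(tr), 1000.0 / rate)


class TestSynthesis:
    def test_null_signal_is_all_zero(self):
        s = make_schedule(1.0, 2, 10, seed=0)
        p = SimParams(alpha_amp=0, n200_amp=0, p300_amp=0, ssvep_amp=0,
                      noise_amp=0, blink_rate_per_min=0, seed=0)
        rec = synthesize_recording(s, p)
        assert np.all(rec.data == 0)

    def test_seed_reproducibility(self):
        s = make_schedule(4.0, 5, 10, seed=2)
        a = synthesize_recording(s, SimParams(seed=5))
        b = synthesize_recording(s, SimParams(seed=5))
        c = synthesize_recording(s, SimParams(seed=6))
        np.testing.assert_array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_ssvep_only_spectrum_peaks_at_harmonics(self):
        s = make_schedule(4.0, 10, 10, seed=4)
        p = SimParams(alpha_amp=0, n200_amp=0, p300_amp=0, noise_amp=0,
                      ssvep_amp=2.0, seed=4)
        rec = synthesize_recording(s, p)
        x = rec.data[rec.channel_index("Oz")]
        amp = np.abs(np.fft.rfft(x))
        freqs = np.fft.rfftfreq(x.size, 1 / rec.fs)
        # brute-force peak bins: strongest bin inside each 1 Hz-wide band
        for f0 in (4.0, 8.0, 12.0):
            band = (freqs > f0 - 0.5) & (freqs < f0 + 0.5)
            peak = freqs[band][np.argmax(amp[band])]
            assert abs(peak - f0) < 0.05

    def test_erd_depth_via_hilbert_envelope_oracle(self):
        s = make_schedule(1.0, 30, 10, seed=7)
        p = SimParams(alpha_amp=4.0, alpha_env_mod=0.0, erd_depth=0.5,
                      n200_amp=0, p300_amp=0, ssvep_amp=0, noise_amp=0,
                      seed=7)
        rec = synthesize_recording(s, p)
        env = np.abs(hilbert(rec.data[rec.channel_index("Oz")]))
        fs = rec.fs
        targ, non = [], []
        for ev in rec.events:
            lo = ev.sample + int(0.35 * fs)   # inside the 300-800 plateau
            hi = ev.sample + int(0.75 * fs)
            (targ if ev.label == TARGET else non).append(env[lo:hi].mean())
        ratio = np.mean(targ) / np.mean(non)
        assert ratio == pytest.approx(0.5, abs=0.05)

    def test_alpha_spectral_peak_at_configured_frequency(self):
        s = make_schedule(1.0, 10, 10, seed=8)
        p = SimParams(alpha_amp=4.0, n200_amp=0, p300_amp=0, ssvep_amp=0,
                      noise_amp=0, erd_depth=0.0, iaf_hz=11.0, seed=8)
        rec = synthesize_recording(s, p)
        x = rec.data[rec.channel_index("Oz")]
        freqs = np.fft.rfftfreq(x.size, 1 / rec.fs)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(x)))]
        assert abs(peak - 11.0) <= freqs[1]   # within one frequency bin

    def test_blinks_are_frontal_dominant(self):
        s = make_schedule(1.0, 5, 10, seed=3)
        quiet = SimParams(alpha_amp=0, n200_amp=0, p300_amp=0, ssvep_amp=0,
                          noise_amp=0, seed=3)
        p = quiet.replace(blink_rate_per_min=10.0)
        rec = synthesize_recording(s, p)
        assert np.abs(rec.data[rec.channel_index("F7")]).max() \
            > 5 * np.abs(rec.data[rec.channel_index("Oz")]).max()

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            SimParams(erd_depth=1.5)
        with pytest.raises(ValueError):
            SimParams(alpha_amp=-1.0)


class TestInjectArtifacts:
    def test_no_injections_gives_empty_truth(self):
        s = make_schedule(1.0, 5, 10, seed=0)
        rec = synthesize_recording(s, SimParams(seed=0))
        out, truth = inject_artifacts(rec, kinds=(), n_per_kind=0)
        assert truth == []
        np.testing.assert_array_equal(out.data, rec.data)

    def test_injection_ground_truth_kinds(self):
        s = make_schedule(1.0, 10, 10, seed=1)
        rec = synthesize_recording(s, SimParams(seed=1))
        out, truth = inject_artifacts(rec, n_per_kind=2, seed=1)
        assert len(truth) == 2 * len(ARTIFACT_KINDS)
        assert {k for _, k in truth} == set(ARTIFACT_KINDS)
        # contaminated epochs are distinct
        assert len({i for i, _ in truth}) == len(truth)
        # data actually changed
        assert not np.array_equal(out.data, rec.data)
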