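"""Synthetic RSVP calibration schedules and EEG recordings.

A calibration consists of 100 trials. Each trial shows the target letter
prompt for 1 s, a red fixation cross for 500 ms, then a 10-letter
sequence at the presentation rate (1 Hz or 4 Hz); a 750 ms blank screen
separates consecutive trials. Exactly one letter per sequence is the
target, so a full calibration yields 100 target and 900 non-target
stimulus events.

The synthesizer emulates the phenomenology that the downstream analyses
measure: posterior-dominant alpha near a configurable individual alpha
frequency, whose envelope is attenuated by a fraction ``erd_depth``
300-800 ms after target onsets; N200/P300 transients on target epochs;
a steady-state visual response at the presentation rate and its 2nd/3rd
harmonics, phase-locked to each sequence; 1/f background noise; and
optional frontal-dominant blink transients. None of this pretends to be
cortical physiology - it is the minimal signal content needed to make
every pipeline stage verifiable against known ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .config import ALPHABET, CHANNELS

TARGET = "target"
NONTARGET = "nontarget"

#: Relative channel gains (posterior-dominant alpha topography).
DEFAULT_ALPHA_GAINS: Dict[str, float] = {
    "Oz": 1.0, "PO7": 0.9, "PO8": 0.9, "Pz": 0.8,
    "P4": 0.5, "FCz": 0.2, "F7": 0.1,
}
#: N200: posterior negativity.
N200_TOPOGRAPHY: Dict[str, float] = {
    "Oz": 1.0, "PO7": 0.9, "PO8": 0.9, "Pz": 0.7,
    "P4": 0.5, "FCz": 0.3, "F7": 0.1,
}
#: P300: Pz-dominant positivity.
P300_TOPOGRAPHY: Dict[str, float] = {
    "Pz": 1.0, "P4": 0.7, "Oz": 0.5, "PO7": 0.5, "PO8": 0.5,
    "FCz": 0.4, "F7": 0.1,
}
#: Blinks project mostly onto the anterior sites.
BLINK_TOPOGRAPHY: Dict[str, float] = {
    "F7": 1.0, "FCz": 0.8, "Pz": 0.15, "P4": 0.1,
    "PO7": 0.05, "PO8": 0.05, "Oz": 0.05,
}


# ---------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusEvent:
    onset_ms: float
    label: str              # TARGET or NONTARGET
    trial: int
    position: int           # 0-based position within the sequence
    letter: str


@dataclass
class StimulusSchedule:
    rate_hz: float
    n_trials: int
    seq_len: int
    events: List[StimulusEvent]
    prompt_ms: float = 1000.0
    fixation_ms: float = 500.0
    inter_sequence_ms: float = 750.0

    @property
    def soa_ms(self) -> float:
        """Stimulus-onset asynchrony within a sequence."""
        return 1000.0 / self.rate_hz

    @property
    def trial_duration_ms(self) -> float:
        return (self.prompt_ms + self.fixation_ms
                + self.seq_len * self.soa_ms + self.inter_sequence_ms)

    @property
    def duration_ms(self) -> float:
        """End of the last trial's inter-sequence gap."""
        return self.n_trials * self.trial_duration_ms

    @property
    def n_targets(self) -> int:
        return sum(e.label == TARGET for e in self.events)

    @property
    def n_nontargets(self) -> int:
        return sum(e.label == NONTARGET for e in self.events)

    def onsets_ms(self) -> np.ndarray:
        return np.array([e.onset_ms for e in self.events])

    def labels(self) -> np.ndarray:
        return np.array([e.label for e in self.events])


def make_schedule(rate_hz: float, n_trials: int, seq_len: int,
                  seed: int = 0) -> StimulusSchedule:
    """Build one calibration's event timeline.

    The target position within each sequence is drawn uniformly from the
    ``seq_len`` positions; sequence letters are sampled without
    replacement from the 28-character alphabet so the target letter
    appears exactly once per sequence.
    """
    if rate_hz <= 0:
        raise ValueError(f"rate_hz must be positive, got {rate_hz}")
    if seq_len < 1:
        raise ValueError(f"seq_len must be >= 1, got {seq_len}")
    if n_trials < 0:
        raise ValueError(f"n_trials must be >= 0, got {n_trials}")

    rng = np.random.default_rng(seed)
    sched = StimulusSchedule(rate_hz=rate_hz, n_trials=n_trials,
                             seq_len=seq_len, events=[])
    soa = sched.soa_ms
    for trial in range(n_trials):
        t0 = trial * sched.trial_duration_ms
        seq_start = t0 + sched.prompt_ms + sched.fixation_ms
        target_pos = int(rng.integers(seq_len))
        target_letter = ALPHABET[int(rng.integers(len(ALPHABET)))]
        others = [a for a in ALPHABET if a != target_letter]
        n_other = seq_len - 1
        if n_other <= len(others):
            fill = list(rng.choice(others, size=n_other, replace=False))
        else:  # sequences longer than the alphabet: allow repeats
            fill = list(rng.choice(others, size=n_other, replace=True))
        letters = fill[:target_pos] + [target_letter] + fill[target_pos:]
        for pos in range(seq_len):
            sched.events.append(StimulusEvent(
                onset_ms=seq_start + pos * soa,
                label=TARGET if pos == target_pos else NONTARGET,
                trial=trial, position=pos, letter=letters[pos]))
    return sched


# ---------------------------------------------------------------------
# Recording container
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class Marker:
    sample: int
    label: str
    trial: int = -1
    position: int = -1


@dataclass
class RawRecording:
    data: np.ndarray            # channel x sample, microvolts
    fs: float
    channels: Tuple[str, ...]
    events: List[Marker] = field(default_factory=list)

    def __post_init__(self):
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        for ev in self.events:
            if not (0 <= ev.sample < self.data.shape[1]):
                raise ValueError(
                    f"event sample {ev.sample} outside recording "
                    f"of {self.data.shape[1]} samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in {self.channels}")

    def copy(self) -> "RawRecording":
        return RawRecording(self.data.copy(), self.fs,
                            tuple(self.channels), list(self.events))


# ---------------------------------------------------------------------
# Simulation parameters
# ---------------------------------------------------------------------

@dataclass
class SimParams:
    """Generator settings for one synthetic calibration recording.

    Amplitudes are in microvolts at the strongest channel; the per-channel
    gain maps spread each component over the montage. ``erd_depth`` is the
    fractional attenuation of the alpha envelope inside ``erd_window_ms``
    after each target onset (0 = no effect, 1 = complete suppression).
    """
    iaf_hz: float = 10.0
    alpha_amp: float = 4.0
    #: Fractional slow (< 1.5 Hz) random modulation of the alpha envelope.
    alpha_env_mod: float = 0.3
    erd_depth: float = 0.5
    erd_window_ms: Tuple[float, float] = (300.0, 800.0)
    erd_ramp_ms: float = 50.0
    n200_amp: float = 5.0
    p300_amp: float = 10.0
    n200_lat_ms: float = 250.0
    p300_lat_ms: float = 375.0
    erp_sigma_ms: float = 25.0
    ssvep_amp: float = 2.0
    #: 2nd and 3rd harmonic amplitudes relative to the fundamental.
    ssvep_harmonics: Tuple[float, float] = (0.6, 0.4)
    noise_amp: float = 4.0          # broadband RMS, microvolts
    noise_exponent: float = 1.0     # 1/f^exponent power slope
    blink_rate_per_min: float = 0.0
    blink_amp: float = 150.0
    channel_gains: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ALPHA_GAINS))
    fs: float = 300.0
    seed: int = 0
    tail_pad_ms: float = 1500.0

    def __post_init__(self):
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must lie in [0, 1]")
        for name in ("alpha_amp", "n200_amp", "p300_amp", "ssvep_amp",
                     "noise_amp", "blink_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.fs <= 2 * self.iaf_hz:
            raise ValueError("fs must exceed twice the alpha frequency")

    def replace(self, **kw) -> "SimParams":
        return dataclasses.replace(self, **kw)


def reference_scenario(seed: int = 0) -> SimParams:
    """The default simulation conditions used throughout the test suite."""
    return SimParams(seed=seed)


def null_scenario(seed: int = 0) -> SimParams:
    """No target-locked signal at all: ERD depth 0 and ERP amplitudes 0.

    Under this scenario target and non-target epochs are exchangeable, so
    any within-calibration target/non-target test operates under its null
    hypothesis. (Keeping the ERP templates on with d = 0 would leave a
    deterministic target-locked transient whose spectral skirt reaches the
    4-16 Hz band and would invalidate the null.)
    """
    return SimParams(erd_depth=0.0, n200_amp=0.0, p300_amp=0.0, seed=seed)


# ---------------------------------------------------------------------
# Synthesis
# ---------------------------------------------------------------------

def _powerlaw_noise(rng: np.random.Generator, n_ch: int, n_samp: int,
                    fs: float, exponent: float, rms: float) -> np.ndarray:
    """Gaussian noise with power spectral density ~ 1/f**exponent."""
    if rms == 0:
        return np.zeros((n_ch, n_samp))
    freqs = np.fft.rfftfreq(n_samp, 1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal((n_ch, freqs.size))
            + 1j * rng.standard_normal((n_ch, freqs.size))) * shape
    x = np.fft.irfft(spec, n=n_samp, axis=1)
    x *= rms / x.std(axis=1, keepdims=True)
    return x


def _slow_envelope(rng: np.random.Generator, n_samp: int, fs: float,
                   mod: float) -> np.ndarray:
    """Multiplicative alpha envelope: 1 + mod * lowpassed unit noise."""
    if mod == 0:
        return np.ones(n_samp)
    from scipy.signal import butter, sosfiltfilt
    sos = butter(2, 1.5, btype="low", fs=fs, output="sos")
    slow = sosfiltfilt(sos, rng.standard_normal(n_samp))
    slow /= max(slow.std(), 1e-12)
    return np.clip(1.0 + mod * slow, 0.05, None)


def _raised_cosine_gate(t: np.ndarray, start: float, stop: float,
                        ramp: float) -> np.ndarray:
    """1 inside [start, stop], raised-cosine ramps of width ``ramp`` (s)."""
    g = np.zeros_like(t)
    if ramp <= 0:
        g[(t >= start) & (t < stop)] = 1.0
        return g
    core = (t >= start + ramp) & (t <= stop - ramp)
    g[core] = 1.0
    up = (t >= start) & (t < start + ramp)
    g[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - start) / ramp))
    down = (t > stop - ramp) & (t <= stop)
    g[down] = 0.5 * (1 - np.cos(np.pi * (stop - t[down]) / ramp))
    return g


def synthesize_recording(schedule: StimulusSchedule,
                         params: SimParams) -> RawRecording:
    """Render a schedule into a continuous multichannel recording.

    Deterministic given ``params.seed``. The recording is padded past the
    final trial so that the widest analysis epoch fits around every event.
    """
    fs = params.fs
    duration_ms = schedule.duration_ms + params.tail_pad_ms
    n_samp = max(int(round(duration_ms / 1000.0 * fs)), 1)
    n_ch = len(CHANNELS)
    t = np.arange(n_samp) / fs
    rng = np.random.default_rng(params.seed)

    gains = np.array([params.channel_gains.get(ch, 0.0) for ch in CHANNELS])
    data = _powerlaw_noise(rng, n_ch, n_samp, fs,
                           params.noise_exponent, params.noise_amp)

    onsets_s = schedule.onsets_ms() / 1000.0 if schedule.events else np.array([])
    labels = schedule.labels() if schedule.events else np.array([])
    target_onsets = onsets_s[labels == TARGET] if schedule.events else []

    # --- posterior alpha with target-locked attenuation ----------------
    if params.alpha_amp > 0:
        envelope = _slow_envelope(rng, n_samp, fs, params.alpha_env_mod)
        erd_gain = np.ones(n_samp)
        w0, w1 = (w / 1000.0 for w in params.erd_window_ms)
        ramp = params.erd_ramp_ms / 1000.0
        for onset in target_onsets:
            erd_gain -= params.erd_depth * _raised_cosine_gate(
                t, onset + w0, onset + w1, ramp)
        np.clip(erd_gain, 0.0, None, out=erd_gain)
        phase0 = rng.uniform(0, 2 * np.pi)
        alpha = (params.alpha_amp * envelope * erd_gain
                 * np.sin(2 * np.pi * params.iaf_hz * t + phase0))
        data += gains[:, None] * alpha[None, :]

    # --- steady-state visual response during each sequence -------------
    if params.ssvep_amp > 0 and schedule.events:
        ssvep_gains = np.array(
            [DEFAULT_ALPHA_GAINS.get(ch, 0.0) for ch in CHANNELS])
        amps = (1.0,) + tuple(params.ssvep_harmonics)
        wave = np.zeros(n_samp)
        soa_s = schedule.soa_ms / 1000.0
        for trial in range(schedule.n_trials):
            trial_events = [e for e in schedule.events if e.trial == trial]
            if not trial_events:
                continue
            start = trial_events[0].onset_ms / 1000.0
            stop = trial_events[-1].onset_ms / 1000.0 + soa_s
            gate = _raised_cosine_gate(t, start, stop, 0.05)
            active = gate > 0
            ta = t[active] - start
            s = np.zeros(ta.size)
            for k, a in enumerate(amps, start=1):
                s += a * np.sin(2 * np.pi * k * schedule.rate_hz * ta)
            wave[active] += gate[active] * s
        data += params.ssvep_amp * ssvep_gains[:, None] * wave[None, :]

    # --- ERP templates on target epochs --------------------------------
    if (params.n200_amp > 0 or params.p300_amp > 0) and len(target_onsets):
        sig = params.erp_sigma_ms / 1000.0
        n200_g = np.array([N200_TOPOGRAPHY.get(ch, 0.0) for ch in CHANNELS])
        p300_g = np.array([P300_TOPOGRAPHY.get(ch, 0.0) for ch in CHANNELS])
        half = 4 * sig
        for onset in target_onsets:
            lo = max(int((onset + min(params.n200_lat_ms,
                                      params.p300_lat_ms) / 1000.0
                          - half) * fs), 0)
            hi = min(int((onset + max(params.n200_lat_ms,
                                      params.p300_lat_ms) / 1000.0
                          + half) * fs) + 1, n_samp)
            tt = t[lo:hi] - onset
            n200 = -params.n200_amp * np.exp(
                -0.5 * ((tt - params.n200_lat_ms / 1000.0) / sig) ** 2)
            p300 = params.p300_amp * np.exp(
                -0.5 * ((tt - params.p300_lat_ms / 1000.0) / sig) ** 2)
            data[:, lo:hi] += (n200_g[:, None] * n200[None, :]
                               + p300_g[:, None] * p300[None, :])

    # --- blink transients ----------------------------------------------
    if params.blink_rate_per_min > 0 and params.blink_amp > 0:
        n_blinks = rng.poisson(params.blink_rate_per_min
                               * duration_ms / 60000.0)
        blink_g = np.array([BLINK_TOPOGRAPHY.get(ch, 0.0) for ch in CHANNELS])
        tb = np.arange(int(0.4 * fs)) / fs
        template = (np.exp(-0.5 * ((tb - 0.15) / 0.05) ** 2)
                    - 0.35 * np.exp(-0.5 * ((tb - 0.30) / 0.08) ** 2))
        template *= params.blink_amp / template.max()
        starts = rng.uniform(0, duration_ms / 1000.0 - 0.4, size=n_blinks)
        for s0 in np.sort(starts):
            i0 = int(s0 * fs)
            seg = min(template.size, n_samp - i0)
            data[:, i0:i0 + seg] += blink_g[:, None] * template[None, :seg]

    markers = [Marker(sample=int(round(e.onset_ms / 1000.0 * fs)),
                      label=e.label, trial=e.trial, position=e.position)
               for e in schedule.events]
    return RawRecording(data=data, fs=fs, channels=tuple(CHANNELS),
                        events=markers)


# ---------------------------------------------------------------------
# Artifact injection (ground truth for the rejection rules)
# ---------------------------------------------------------------------

ARTIFACT_KINDS = ("gradient", "difference", "absolute", "low_activity")


def inject_artifacts(recording: RawRecording,
                     kinds: Sequence[str] = ARTIFACT_KINDS,
                     n_per_kind: int = 2,
                     window_ms: Tuple[float, float] = (-1250.0, 1250.0),
                     seed: int = 0,
                     margin: float = 1.2,
                     ) -> Tuple[RawRecording, List[Tuple[int, str]]]:
    """Contaminate seeded epochs with known rule violations.

    Each injected violation exceeds its rule threshold by the factor
    ``margin`` (default 20% over threshold) and is built from band-
    limited content so it survives the 1-45 Hz preprocessing filter that
    precedes flagging. Returns the contaminated recording and the
    ground-truth list of (event_index, kind) pairs. Large fast
    transients necessarily violate more than one rule (a supra-threshold
    gradient burst also exceeds the absolute-voltage limit), so ground
    truth records the intended kind while the flagger may report a
    superset of reasons.
    """
    for kind in kinds:
        if kind not in ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind {kind!r}")
    rec = recording.copy()
    fs = rec.fs
    rng = np.random.default_rng(seed)
    n_events = len(rec.events)
    usable = [i for i, ev in enumerate(rec.events)
              if (ev.sample + int(window_ms[0] / 1000.0 * fs) >= 0
                  and ev.sample + int(window_ms[1] / 1000.0 * fs)
                  <= rec.n_samples)]
    need = len(kinds) * n_per_kind
    if need > len(usable):
        raise ValueError("not enough epochs to contaminate")
    chosen = rng.choice(usable, size=need, replace=False)
    truth: List[Tuple[int, str]] = []
    t_rel = None
    for j, kind in enumerate(np.repeat(list(kinds), n_per_kind)):
        idx = int(chosen[j])
        ev = rec.events[idx]
        lo = ev.sample + int(window_ms[0] / 1000.0 * fs)
        hi = ev.sample + int(window_ms[1] / 1000.0 * fs)
        n = hi - lo
        t_rel = np.arange(n) / fs
        center = n // 2
        def _burst(freq_hz: float, amp: float, dur_s: float) -> None:
            w = int(dur_s * fs)
            tt = np.arange(w) / fs
            gate = _raised_cosine_gate(tt, 0.0, dur_s, 0.03)
            seg = amp * gate * np.sin(2 * np.pi * freq_hz * tt)
            rec.data[:, lo + center:lo + center + w] += seg[None, :]

        if kind == "absolute":
            # in-band 10 Hz burst: supra-threshold amplitude, slope well
            # under the gradient limit (~5.7 uV/ms at 90 uV)
            _burst(10.0, 75.0 * margin, 0.3)
        elif kind == "gradient":
            # fast in-band oscillation; amplitude chosen so the discrete
            # slope 2*A*sin(pi*f/fs')*fs'/1000 exceeds the limit by the
            # margin even after ~13% band-edge attenuation at 40 Hz
            fs_out = 150.0
            amp = (50.0 * margin * 1000.0
                   / (2 * np.sin(np.pi * 40.0 / fs_out) * fs_out) / 0.8)
            _burst(40.0, amp, 0.2)
        elif kind == "difference":
            # 15 Hz burst: peak-to-peak range 2*A inside any 50 ms window
            _burst(15.0, 125.0 * margin / 2.0, 0.3)
        elif kind == "low_activity":
            # electrode drop-out: long near-flat segment; its middle stays
            # below the activity floor after filter ring-down
            dur = int(1.0 * fs)
            rec.data[:, lo + center:lo + center + dur] *= 0.001
        truth.append((idx, str(kind)))
    return rec, truth
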