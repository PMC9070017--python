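"""Filtering, resampling, channel pooling and stimulus-locked epoching.

The processing chain is: zero-phase Butterworth band-pass 1-45 Hz with a
48 dB/octave design slope plus a 60 Hz notch, downsampling 300 -> 150 Hz,
an optional virtual "POOL" channel averaging the occipitoparietal sites,
and segmentation into stimulus-locked epochs. All filters operate on the
continuous recording; epochs are cut afterwards, so filtering and
epoching commute by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal

from .config import POOL, POSTERIOR_CHANNELS
from .sim import Marker, RawRecording

logger = logging.getLogger(__name__)


def bandpass_notch(recording: RawRecording, low_hz: float = 1.0,
                   high_hz: float = 45.0, notch_hz: float = 60.0,
                   order: int = 8, notch_q: float = 30.0) -> RawRecording:
    """Zero-phase band-pass + notch of the continuous recording.

    The band-pass is an order-8 Butterworth (6 dB/octave per order gives
    the 48 dB/octave design slope), applied forward and backward; the
    notch is a second-order IIR notch, also applied forward-backward.
    """
    nyq = recording.fs / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band edges must satisfy 0 < {low_hz} < {high_hz} < {nyq}")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=recording.fs, output="sos")
    data = signal.sosfiltfilt(sos, recording.data, axis=1)
    if notch_hz is not None and notch_hz < nyq:
        b, a = signal.iirnotch(notch_hz, notch_q, fs=recording.fs)
        data = signal.filtfilt(b, a, data, axis=1)
    return RawRecording(data=data, fs=recording.fs,
                        channels=tuple(recording.channels),
                        events=list(recording.events))


def resample(recording: RawRecording, target_fs: float) -> RawRecording:
    """Polyphase resampling; event sample indices are rescaled."""
    if target_fs > recording.fs:
        raise ValueError("target_fs must not exceed the recording rate")
    if target_fs == recording.fs:
        return recording.copy()
    frac = Fraction(target_fs / recording.fs).limit_denominator(1000)
    data = signal.resample_poly(recording.data, frac.numerator,
                                frac.denominator, axis=1)
    ratio = target_fs / recording.fs
    events = [Marker(sample=int(round(ev.sample * ratio)), label=ev.label,
                     trial=ev.trial, position=ev.position)
              for ev in recording.events]
    n = data.shape[1]
    events = [ev for ev in events if ev.sample < n]
    return RawRecording(data=data, fs=target_fs,
                        channels=tuple(recording.channels), events=events)


def pool_channels(recording: RawRecording,
                  subset: Sequence[str] = POSTERIOR_CHANNELS,
                  ) -> RawRecording:
    """Append the virtual POOL channel: samplewise mean of ``subset``."""
    idx = [recording.channel_index(ch) for ch in subset]
    pooled = recording.data[idx].mean(axis=0, keepdims=True)
    return RawRecording(data=np.vstack([recording.data, pooled]),
                        fs=recording.fs,
                        channels=tuple(recording.channels) + (POOL,),
                        events=list(recording.events))


@dataclass
class EpochSet:
    """Stimulus-locked epochs: epoch x channel x sample, with labels."""
    data: np.ndarray
    window_ms: Tuple[float, float]
    fs: float
    labels: np.ndarray                   # class per epoch
    channels: Tuple[str, ...]
    trials: np.ndarray = None            # trial index per epoch
    dropped: List[int] = field(default_factory=list)

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal epoch count")
        if self.trials is None:
            self.trials = np.full(self.data.shape[0], -1)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def times_ms(self) -> np.ndarray:
        """Sample times relative to stimulus onset (half-open window)."""
        off = int(round(self.window_ms[0] / 1000.0 * self.fs))
        return (np.arange(self.n_samples) + off) / self.fs * 1000.0

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in {self.channels}")

    def window_slice(self, window_ms: Tuple[float, float]) -> slice:
        """Sample slice for a half-open [start, end) window in ms."""
        off = int(round(self.window_ms[0] / 1000.0 * self.fs))
        a = int(round(window_ms[0] / 1000.0 * self.fs)) - off
        b = int(round(window_ms[1] / 1000.0 * self.fs)) - off
        if a < 0 or b > self.n_samples or a >= b:
            raise ValueError(
                f"window {window_ms} ms outside epoch {self.window_ms} ms")
        return slice(a, b)


def epoch(recording: RawRecording,
          window_ms: Tuple[float, float]) -> EpochSet:
    """Cut one epoch per event from the half-open window [start, end) ms.

    Stimulus onset maps to the sample at t = 0. Events whose window does
    not fit inside the recording are dropped with a logged warning.
    """
    start_ms, end_ms = window_ms
    if start_ms >= end_ms:
        raise ValueError("window start must precede end")
    fs = recording.fs
    off = int(round(start_ms / 1000.0 * fs))
    count = int(round((end_ms - start_ms) / 1000.0 * fs))
    segments, labels, trials, dropped = [], [], [], []
    for i, ev in enumerate(recording.events):
        lo = ev.sample + off
        hi = lo + count
        if lo < 0 or hi > recording.n_samples:
            dropped.append(i)
            continue
        segments.append(recording.data[:, lo:hi])
        labels.append(ev.label)
        trials.append(ev.trial)
    if dropped:
        logger.warning("dropped %d/%d epochs outside recording bounds: %s",
                       len(dropped), len(recording.events), dropped[:10])
    data = (np.stack(segments, axis=0) if segments
            else np.empty((0, recording.data.shape[0], count)))
    return EpochSet(data=data, window_ms=(float(start_ms), float(end_ms)),
                    fs=fs, labels=np.array(labels, dtype=object),
                    channels=tuple(recording.channels),
                    trials=np.array(trials, dtype=int), dropped=dropped)


def preprocess(recording: RawRecording, low_hz: float = 1.0,
               high_hz: float = 45.0, notch_hz: float = 60.0,
               order: int = 8, notch_q: float = 30.0,
               target_fs: Optional[float] = 150.0,
               pool: bool = True) -> RawRecording:
    """Standard chain: band-pass + notch, downsample, append POOL."""
    rec = bandpass_notch(recording, low_hz, high_hz, notch_hz,
                         order=order, notch_q=notch_q)
    if target_fs is not None:
        rec = resample(rec, target_fs)
    if pool:
        rec = pool_channels(rec)
    return rec
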