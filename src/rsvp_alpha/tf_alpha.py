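"""Continuous wavelet transform and target-related alpha attenuation.

Epochs are transformed with a complex Morlet wavelet (Morlet parameter
c = 5) over 48 logarithmically spaced layers from 4 to 16 Hz, each
scaled wavelet carrying unit energy. Complex output is converted to
magnitude; each epoch is then Z-transformed against its own 500 ms
pre-stimulus baseline (-600 to -100 ms), and "alpha activity" is the
mean Z over the 300-800 ms response window at the single layer closest
to the individual alpha frequency. The alpha attenuation effect is the
difference between the target and non-target class medians of that
quantity; a Mann-Whitney U test compares the two classes within a
calibration.

Numerical note: with unit-energy (L2) normalisation the magnitude
response of a Morlet layer to a pure tone peaks at a scale slightly
larger than c/(2 pi f). The scale map used here,
``s = (c + delta) / (2 pi f)`` with ``delta = (sqrt(c^2+2) - c)/2``,
absorbs that offset so that each layer's magnitude response is maximal
exactly at its nominal center frequency; it agrees with the
conventional map to O(1/c^2). See docs/methods.md.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sstats
from scipy.fft import fft, ifft, next_fast_len

from .preprocess import EpochSet

logger = logging.getLogger(__name__)

MORLET_C = 5.0


def layer_frequencies(f_min: float = 4.0, f_max: float = 16.0,
                      n_layers: int = 48) -> np.ndarray:
    """Logarithmically spaced layer center frequencies, inclusive."""
    return f_min * (f_max / f_min) ** (np.arange(n_layers) / (n_layers - 1))


def _scale_for_frequency(f: np.ndarray, c: float = MORLET_C) -> np.ndarray:
    delta = (np.sqrt(c * c + 2.0) - c) / 2.0
    return (c + delta) / (2.0 * np.pi * np.asarray(f, dtype=float))


@dataclass
class Scaleogram:
    """Time-frequency array: epoch x channel x layer x sample."""
    data: np.ndarray
    layer_freqs: np.ndarray
    units: str                           # "magnitude_uV" | "zscore"
    window_ms: Tuple[float, float]
    fs: float
    labels: np.ndarray
    channels: Tuple[str, ...]
    baseline_window_ms: Optional[Tuple[float, float]] = None
    degenerate: List[int] = field(default_factory=list)

    def __post_init__(self):
        if np.any(np.diff(self.layer_freqs) <= 0):
            raise ValueError("layer frequencies must be strictly increasing")
        if self.data.ndim != 4:
            raise ValueError("scaleogram data must be 4-D")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in {self.channels}")

    def window_slice(self, window_ms: Tuple[float, float]) -> slice:
        off = int(round(self.window_ms[0] / 1000.0 * self.fs))
        a = int(round(window_ms[0] / 1000.0 * self.fs)) - off
        b = int(round(window_ms[1] / 1000.0 * self.fs)) - off
        n = self.data.shape[-1]
        if a < 0 or b > n or a >= b:
            raise ValueError(
                f"window {window_ms} ms outside epoch {self.window_ms} ms")
        return slice(a, b)


def cwt_scaleogram(epochs: EpochSet,
                   layer_freqs: Optional[np.ndarray] = None,
                   channels: Optional[Sequence[str]] = None,
                   c: float = MORLET_C,
                   chunk: int = 128) -> Scaleogram:
    """Morlet CWT magnitude of every epoch, channel and layer.

    Implemented as a zero-padded FFT filterbank: each layer multiplies
    the epoch spectrum by the analytic, unit-energy Morlet frequency
    response (a one-sided Gaussian), so no time-domain truncation is
    involved. ``channels`` restricts the transform (and memory) to a
    subset; ``layer_freqs`` defaults to the full 48-layer grid.
    """
    if layer_freqs is None:
        layer_freqs = layer_frequencies()
    layer_freqs = np.atleast_1d(np.asarray(layer_freqs, dtype=float))
    if channels is None:
        ch_idx = list(range(len(epochs.channels)))
        ch_names = tuple(epochs.channels)
    else:
        ch_idx = [epochs.channel_index(ch) for ch in channels]
        ch_names = tuple(channels)

    fs = epochs.fs
    n = epochs.n_samples
    scales = _scale_for_frequency(layer_freqs, c)
    support = 2.0 * 2.5 * scales.max()          # +-2.5 sigma_t, seconds
    if n / fs < support:
        raise ValueError(
            f"epoch of {n / fs:.3f} s shorter than the {support:.3f} s "
            f"wavelet support at {layer_freqs.min():.2f} Hz")

    pad = int(np.ceil(4.0 * scales.max() * fs))
    nfft = next_fast_len(n + 2 * pad)
    omega = 2.0 * np.pi * np.fft.fftfreq(nfft, 1.0 / fs)
    # unit-energy analytic Morlet: FT of s^-1/2 psi(t/s) with
    # psi(t) = pi^-1/4 exp(i c t) exp(-t^2/2)
    resp = (np.sqrt(scales[:, None]) * np.pi ** (-0.25) * np.sqrt(2 * np.pi)
            * np.exp(-0.5 * (scales[:, None] * omega[None, :] - c) ** 2))

    x = epochs.data[:, ch_idx, :]
    out = np.empty((x.shape[0], len(ch_idx), layer_freqs.size, n))
    for lo in range(0, x.shape[0], chunk):
        hi = min(lo + chunk, x.shape[0])
        spec = fft(x[lo:hi], n=nfft, axis=-1)
        w = ifft(spec[:, :, None, :] * resp[None, None, :, :], axis=-1)
        out[lo:hi] = np.abs(w[..., :n])
    return Scaleogram(data=out, layer_freqs=layer_freqs,
                      units="magnitude_uV", window_ms=epochs.window_ms,
                      fs=fs, labels=np.asarray(epochs.labels),
                      channels=ch_names)


def cwt_scaleogram_pywt(epochs: EpochSet,
                        layer_freqs: Optional[np.ndarray] = None,
                        channels: Optional[Sequence[str]] = None,
                        bandwidth: float = 1.5,
                        center_freq: float = 1.0) -> Scaleogram:
    """Classifier-side wavelet variant: PyWavelets complex Morlet
    ("cmor1.5-1.0") with unnormalised scales, as used for the
    feature-extraction pipeline. Parameterisation differs from the
    unit-energy transform; both are provided because the two analysis
    strands used different software.
    """
    import pywt

    if layer_freqs is None:
        layer_freqs = layer_frequencies()
    layer_freqs = np.atleast_1d(np.asarray(layer_freqs, dtype=float))
    if channels is None:
        ch_idx = list(range(len(epochs.channels)))
        ch_names = tuple(epochs.channels)
    else:
        ch_idx = [epochs.channel_index(ch) for ch in channels]
        ch_names = tuple(channels)
    wav = pywt.ContinuousWavelet(f"cmor{bandwidth}-{center_freq}")
    scales = center_freq * epochs.fs / layer_freqs
    x = epochs.data[:, ch_idx, :]
    flat = x.reshape(-1, x.shape[-1])
    coef, _ = pywt.cwt(flat, scales, wav, axis=-1)
    # pywt returns (n_scales, n_signals, n_samples)
    mag = np.abs(coef).transpose(1, 0, 2).reshape(
        x.shape[0], len(ch_idx), layer_freqs.size, x.shape[-1])
    return Scaleogram(data=mag, layer_freqs=layer_freqs,
                      units="magnitude_uV", window_ms=epochs.window_ms,
                      fs=epochs.fs, labels=np.asarray(epochs.labels),
                      channels=ch_names)


def ztransform(scaleogram: Scaleogram,
               baseline_window_ms: Tuple[float, float] = (-600.0, -100.0),
               ) -> Scaleogram:
    """Z-score every sample against the epoch's own baseline statistics.

    The mean and standard deviation are taken per epoch, per channel and
    per layer over the baseline samples. Epochs with zero baseline
    deviation in any channel/layer are degenerate; they are excluded
    from the output and logged.
    """
    if scaleogram.units != "magnitude_uV":
        raise ValueError("ztransform expects magnitude input")
    sl = scaleogram.window_slice(baseline_window_ms)
    base = scaleogram.data[..., sl]
    mu = base.mean(axis=-1, keepdims=True)
    sd = base.std(axis=-1, keepdims=True)
    degenerate = np.flatnonzero((sd == 0).any(axis=(1, 2, 3)))
    keep = np.ones(scaleogram.n_epochs, dtype=bool)
    keep[degenerate] = False
    if degenerate.size:
        logger.warning("excluding %d degenerate epochs (zero baseline SD)",
                       degenerate.size)
    z = (scaleogram.data[keep] - mu[keep]) / sd[keep]
    return Scaleogram(data=z, layer_freqs=scaleogram.layer_freqs,
                      units="zscore", window_ms=scaleogram.window_ms,
                      fs=scaleogram.fs, labels=scaleogram.labels[keep],
                      channels=tuple(scaleogram.channels),
                      baseline_window_ms=tuple(baseline_window_ms),
                      degenerate=[int(i) for i in degenerate])


def select_iaf_layer(scaleogram_or_freqs, iaf_hz: float) -> int:
    """Index of the layer whose center frequency is closest to the IAF;
    ties break toward the lower frequency."""
    freqs = (scaleogram_or_freqs.layer_freqs
             if isinstance(scaleogram_or_freqs, Scaleogram)
             else np.asarray(scaleogram_or_freqs))
    return int(np.argmin(np.abs(freqs - iaf_hz)))


@dataclass
class AlphaMeasures:
    per_epoch: np.ndarray            # mean Z in the response window
    labels: np.ndarray
    class_medians: dict
    attenuation: float               # target median - non-target median
    mwu_u: float
    mwu_p: float
    baseline_window_ms: Tuple[float, float]
    response_window_ms: Tuple[float, float]
    source: str


def alpha_activity(scaleogram_z: Scaleogram, layer: int,
                   response_window_ms: Tuple[float, float] = (300.0, 800.0),
                   source: str = "POOL") -> AlphaMeasures:
    """Per-epoch alpha activity, class medians and the attenuation effect.

    Negative attenuation means target alpha fell below non-target alpha
    (event-related desynchronisation following targets).
    """
    if scaleogram_z.units != "zscore":
        raise ValueError("alpha_activity expects Z-scored input")
    ci = scaleogram_z.channel_index(source)
    sl = scaleogram_z.window_slice(response_window_ms)
    per_epoch = scaleogram_z.data[:, ci, layer, sl].mean(axis=-1)
    labels = scaleogram_z.labels
    from .sim import NONTARGET, TARGET
    t = per_epoch[labels == TARGET]
    n = per_epoch[labels == NONTARGET]
    if t.size == 0 or n.size == 0:
        raise ValueError("both classes must contain at least one epoch")
    medians = {TARGET: float(np.median(t)), NONTARGET: float(np.median(n))}
    u, p = sstats.mannwhitneyu(t, n, alternative="two-sided")
    return AlphaMeasures(per_epoch=per_epoch, labels=labels,
                         class_medians=medians,
                         attenuation=medians[TARGET] - medians[NONTARGET],
                         mwu_u=float(u), mwu_p=float(p),
                         baseline_window_ms=scaleogram_z.baseline_window_ms,
                         response_window_ms=tuple(response_window_ms),
                         source=source)


def estimate_erd_depth(scaleogram_mag: Scaleogram, layer: int,
                       response_window_ms: Tuple[float, float]
                       = (300.0, 800.0),
                       source: str = "POOL") -> float:
    """Recover the fractional envelope attenuation from magnitude data.

    The class-average magnitude time course at the chosen layer is formed
    for each class; the depth estimate is one minus the minimum of the
    target/non-target ratio inside the response window. The minimum (not
    the window mean) is used because attenuation ramps and wavelet
    smoothing dilute the window average of the latent depth, while the
    plateau center retains it.
    """
    if scaleogram_mag.units != "magnitude_uV":
        raise ValueError("depth estimation expects magnitude input")
    from .sim import NONTARGET, TARGET
    ci = scaleogram_mag.channel_index(source)
    labels = scaleogram_mag.labels
    env_t = scaleogram_mag.data[labels == TARGET, ci, layer, :].mean(axis=0)
    env_n = scaleogram_mag.data[labels == NONTARGET, ci, layer, :].mean(axis=0)
    sl = scaleogram_mag.window_slice(response_window_ms)
    ratio = env_t[sl] / env_n[sl]
    return float(1.0 - ratio.min())
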