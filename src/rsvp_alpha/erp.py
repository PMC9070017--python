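"""Class-average ERP waveforms, N200/P300 peaks and target effects.

Epochs (-200 to +800 ms) are baseline-corrected against the -200..0 ms
pre-stimulus mean, averaged within class, and the target-class average
is searched for the N200 (most negative voltage 200-350 ms) and P300
(most positive voltage 300-450 ms). Component amplitudes for BOTH
classes are the mean voltage over +-4 samples (~53 ms at 150 Hz) around
the latencies labelled on the target average; the target effect is the
target-minus-non-target amplitude difference per component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .preprocess import EpochSet
from .sim import NONTARGET, TARGET

logger = logging.getLogger(__name__)

N200_WINDOW_MS = (200.0, 350.0)
P300_WINDOW_MS = (300.0, 450.0)


def average_erp(epochs: EpochSet,
                baseline_ms: Tuple[float, float] = (-200.0, 0.0),
                ) -> Dict[str, np.ndarray]:
    """Baseline-corrected class-average waveforms (channel x sample)."""
    sl = epochs.window_slice(baseline_ms)
    corrected = epochs.data - epochs.data[..., sl].mean(axis=-1,
                                                        keepdims=True)
    out: Dict[str, np.ndarray] = {}
    for cls in (TARGET, NONTARGET):
        mask = epochs.labels == cls
        if not mask.any():
            raise ValueError(f"no epochs in class {cls!r}")
        out[cls] = corrected[mask].mean(axis=0)
    return out


def _window_index(epochs: EpochSet, avg: np.ndarray, ci: int,
                  window_ms: Tuple[float, float], mode: str) -> float:
    sl = epochs.window_slice(window_ms)
    seg = avg[ci, sl]
    # ties break toward the earliest latency (argmin/argmax are first-hit)
    k = int(np.argmin(seg) if mode == "min" else np.argmax(seg))
    times = epochs.times_ms()[sl]
    return float(times[k])


def detect_peaks(epochs: EpochSet, target_avg: np.ndarray, source: str,
                 n200_window_ms: Tuple[float, float] = N200_WINDOW_MS,
                 p300_window_ms: Tuple[float, float] = P300_WINDOW_MS,
                 ) -> Tuple[float, float]:
    """N200/P300 latencies (ms) from the target-class average."""
    ci = epochs.channel_index(source)
    n200 = _window_index(epochs, target_avg, ci, n200_window_ms, "min")
    p300 = _window_index(epochs, target_avg, ci, p300_window_ms, "max")
    return n200, p300


def peak_amplitude(epochs: EpochSet, avg: np.ndarray, source: str,
                   lat_ms: float, half_width: int = 4) -> float:
    """Mean voltage over ``2*half_width + 1`` samples centred on a
    latency; clipped symmetric windows use the available samples with a
    logged warning."""
    ci = epochs.channel_index(source)
    times = epochs.times_ms()
    k = int(np.argmin(np.abs(times - lat_ms)))
    lo, hi = k - half_width, k + half_width + 1
    if lo < 0 or hi > epochs.n_samples:
        logger.warning("amplitude window at %.0f ms clipped by epoch edge",
                       lat_ms)
        lo, hi = max(lo, 0), min(hi, epochs.n_samples)
    return float(avg[ci, lo:hi].mean())


@dataclass
class ErpSummary:
    source: str
    n200_lat_ms: float
    p300_lat_ms: float
    n200_amp: Dict[str, float]          # class -> microvolts
    p300_amp: Dict[str, float]
    n200_target_effect: float
    p300_target_effect: float


def erp_summary(epochs: EpochSet, source: str,
                baseline_ms: Tuple[float, float] = (-200.0, 0.0),
                ) -> ErpSummary:
    """Full ERP analysis of one calibration for one signal source."""
    averages = average_erp(epochs, baseline_ms)
    n200_lat, p300_lat = detect_peaks(epochs, averages[TARGET], source)
    n200_amp = {cls: peak_amplitude(epochs, averages[cls], source, n200_lat)
                for cls in (TARGET, NONTARGET)}
    p300_amp = {cls: peak_amplitude(epochs, averages[cls], source, p300_lat)
                for cls in (TARGET, NONTARGET)}
    return ErpSummary(
        source=source, n200_lat_ms=n200_lat, p300_lat_ms=p300_lat,
        n200_amp=n200_amp, p300_amp=p300_amp,
        n200_target_effect=n200_amp[TARGET] - n200_amp[NONTARGET],
        p300_target_effect=p300_amp[TARGET] - p300_amp[NONTARGET])
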