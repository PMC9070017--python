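"""Deterministic implementation of the four epoch-rejection rules.

An epoch is flagged when ANY checked channel violates ANY rule:

* ``gradient``     - voltage gradient above 50 uV/ms between adjacent
                     samples;
* ``difference``   - peak-to-peak range above 125 uV within any sliding
                     50 ms window;
* ``absolute``     - absolute voltage above 75 uV anywhere;
* ``low_activity`` - peak-to-peak range below 0.5 uV sustained over any
                     contiguous window of at least 100 ms.

The original procedure was semi-automatic (flag, then visual review);
here the flagging is fully deterministic and the review step is omitted.
Rejection is disabled by default in the main pipeline, mirroring the
primary analyses, and enabled by a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Set

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .preprocess import EpochSet

RULES = ("gradient", "difference", "absolute", "low_activity")


@dataclass
class RejectionReport:
    keep_mask: np.ndarray                     # True = epoch retained
    reasons: Dict[int, Set[str]]              # flagged epoch -> rule names
    retention_by_class: Dict[str, float] = field(default_factory=dict)

    @property
    def n_flagged(self) -> int:
        return int((~self.keep_mask).sum())


def _sliding_range(x: np.ndarray, w: int) -> np.ndarray:
    """Max-min over every contiguous window of w samples (last axis)."""
    hi = maximum_filter1d(x, size=w, axis=-1, mode="nearest")
    lo = minimum_filter1d(x, size=w, axis=-1, mode="nearest")
    r = hi - lo
    # keep only fully covered windows: centred filter pads the edges
    left = (w - 1) // 2
    right = w - 1 - left
    if x.shape[-1] < w:
        return np.full(x.shape[:-1] + (1,), np.nan)
    return r[..., left:x.shape[-1] - right]


def flag_epochs(epochs: EpochSet,
                channels: Optional[Sequence[str]] = None,
                gradient_uv_per_ms: float = 50.0,
                difference_uv: float = 125.0,
                difference_window_ms: float = 50.0,
                absolute_uv: float = 75.0,
                low_activity_uv: float = 0.5,
                low_activity_ms: float = 100.0) -> RejectionReport:
    """Evaluate all four rules on every epoch of ``epochs``.

    ``channels`` restricts the check to a subset (default: every channel
    in the epoch set). Thresholds are exposed but default to the
    published values.
    """
    if epochs.fs is None or epochs.fs <= 0:
        raise ValueError("epoch sampling rate must be known and positive")
    if channels is None:
        idx = list(range(len(epochs.channels)))
    else:
        idx = [epochs.channel_index(ch) for ch in channels]
    x = epochs.data[:, idx, :]
    n_ep = x.shape[0]
    ms_per_sample = 1000.0 / epochs.fs

    reasons: Dict[int, Set[str]] = {}

    def _mark(mask_per_epoch: np.ndarray, rule: str) -> None:
        for i in np.flatnonzero(mask_per_epoch):
            reasons.setdefault(int(i), set()).add(rule)

    if x.shape[-1] >= 2:
        grad = np.abs(np.diff(x, axis=-1)) / ms_per_sample
        _mark(grad.max(axis=(1, 2)) > gradient_uv_per_ms, "gradient")

    w_diff = max(int(round(difference_window_ms / ms_per_sample)), 2)
    if x.shape[-1] >= w_diff:
        rng = _sliding_range(x, w_diff)
        _mark(np.nanmax(rng, axis=(1, 2)) > difference_uv, "difference")

    _mark(np.abs(x).max(axis=(1, 2)) > absolute_uv, "absolute")

    w_low = max(int(round(low_activity_ms / ms_per_sample)), 2)
    if x.shape[-1] >= w_low:
        rng = _sliding_range(x, w_low)
        _mark(np.nanmin(rng, axis=(1, 2)) < low_activity_uv, "low_activity")

    keep = np.ones(n_ep, dtype=bool)
    keep[list(reasons)] = False

    retention: Dict[str, float] = {}
    for cls in np.unique(epochs.labels):
        cls_mask = epochs.labels == cls
        total = int(cls_mask.sum())
        retention[str(cls)] = float(keep[cls_mask].sum() / total) if total \
            else float("nan")
    return RejectionReport(keep_mask=keep, reasons=reasons,
                           retention_by_class=retention)


def apply_rejection(epochs: EpochSet, report: RejectionReport) -> EpochSet:
    """Return a new EpochSet containing only the retained epochs."""
    keep = report.keep_mask
    return EpochSet(data=epochs.data[keep], window_ms=epochs.window_ms,
                    fs=epochs.fs, labels=epochs.labels[keep],
                    channels=tuple(epochs.channels),
                    trials=epochs.trials[keep], dropped=list(epochs.dropped))


def brute_force_flags(epoch_data: np.ndarray, fs: float,
                      **thresholds) -> Set[str]:
    """Reference rule evaluation for a single epoch (channel x sample).

    Pure-Python loops over every sample and window; used as the
    independent oracle for :func:`flag_epochs` in tests.
    """
    g = thresholds.get("gradient_uv_per_ms", 50.0)
    d = thresholds.get("difference_uv", 125.0)
    dw = thresholds.get("difference_window_ms", 50.0)
    a = thresholds.get("absolute_uv", 75.0)
    la = thresholds.get("low_activity_uv", 0.5)
    lam = thresholds.get("low_activity_ms", 100.0)
    ms = 1000.0 / fs
    hits: Set[str] = set()
    for ch in epoch_data:
        n = len(ch)
        for t in range(1, n):
            if abs(ch[t] - ch[t - 1]) / ms > g:
                hits.add("gradient")
        w = max(int(round(dw / ms)), 2)
        for t in range(n - w + 1):
            seg = ch[t:t + w]
            if seg.max() - seg.min() > d:
                hits.add("difference")
        for t in range(n):
            if abs(ch[t]) > a:
                hits.add("absolute")
        w = max(int(round(lam / ms)), 2)
        for t in range(n - w + 1):
            seg = ch[t:t + w]
            if seg.max() - seg.min() < la:
                hits.add("low_activity")
    return hits
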