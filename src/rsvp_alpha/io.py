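"""File I/O: EDF recordings, events CSV, and result tables.

Recordings are exchanged as 16-bit EDF with physical units in
microvolts, with a sidecar ``events.csv`` carrying the stimulus markers
(onset_sample, onset_ms, class, trial, position). EDF reading goes
through ``mne.io.read_raw_edf``; writing uses a minimal EDF writer
implemented here, covering exactly the subset of the format this
package produces (continuous multichannel signals at one sampling
rate). The writer is round-trip tested against the MNE reader.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .sim import Marker, RawRecording


# ---------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------

def _pad(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, recording: RawRecording,
              record_duration_s: float = 1.0) -> None:
    """Write a recording as 16-bit EDF (physical units microvolts).

    The final data record is zero-padded when the recording length is
    not a whole number of records; the true sample count is recoverable
    from the events sidecar or by trimming trailing zeros.
    """
    data = np.asarray(recording.data, dtype=float)
    n_ch, n_samp = data.shape
    spr = int(round(recording.fs * record_duration_s))
    if abs(spr - recording.fs * record_duration_s) > 1e-9:
        raise ValueError("record duration must hold a whole number of "
                         "samples")
    n_rec = int(np.ceil(n_samp / spr))
    pad_samp = n_rec * spr - n_samp

    lim = max(np.abs(data).max(), 1e-6)
    phys_max = float(np.ceil(lim))
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32768
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((data - phys_min) * scale + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")
    if pad_samp:
        zero = np.round((0.0 - phys_min) * scale + dig_min).astype("<i2")
        digital = np.hstack([digital,
                             np.full((n_ch, pad_samp), zero, dtype="<i2")])

    now = datetime.datetime(2000, 1, 1)
    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad("Startdate X X X X", 80),
        _pad(now.strftime("%d.%m.%y"), 8),
        _pad(now.strftime("%H.%M.%S"), 8),
        _pad(str(256 * (1 + n_ch)), 8),
        _pad("", 44),
        _pad(str(n_rec), 8),
        _pad(f"{record_duration_s:g}", 8),
        _pad(str(n_ch), 4),
    ])
    fields = [
        [_pad(ch, 16) for ch in recording.channels],
        [_pad("EEG", 80)] * n_ch,
        [_pad("uV", 8)] * n_ch,
        [_pad(f"{phys_min:g}", 8)] * n_ch,
        [_pad(f"{phys_max:g}", 8)] * n_ch,
        [_pad(str(dig_min), 8)] * n_ch,
        [_pad(str(dig_max), 8)] * n_ch,
        [_pad("", 80)] * n_ch,
        [_pad(str(spr), 8)] * n_ch,
        [_pad("", 32)] * n_ch,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for block in fields:
            fh.write(b"".join(block))
        # data records: per record, all samples of ch1, then ch2, ...
        reshaped = digital.reshape(n_ch, n_rec, spr)
        for r in range(n_rec):
            fh.write(reshaped[:, r, :].tobytes())


def read_edf(path, events: Optional[List[Marker]] = None,
             n_samples: Optional[int] = None) -> RawRecording:
    """Load an EDF file into a RawRecording (microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6          # Volts -> microvolts
    if n_samples is not None:
        data = data[:, :n_samples]
    return RawRecording(data=data, fs=float(raw.info["sfreq"]),
                        channels=tuple(raw.ch_names),
                        events=list(events) if events else [])


# ---------------------------------------------------------------------
# Events CSV
# ---------------------------------------------------------------------

def write_events_csv(path, recording: RawRecording) -> None:
    rows = [{"onset_sample": ev.sample,
             "onset_ms": ev.sample / recording.fs * 1000.0,
             "class": ev.label, "trial": ev.trial,
             "position": ev.position}
            for ev in recording.events]
    pd.DataFrame(rows, columns=["onset_sample", "onset_ms", "class",
                                "trial", "position"]).to_csv(path,
                                                             index=False)


def read_events_csv(path) -> List[Marker]:
    df = pd.read_csv(path)
    return [Marker(sample=int(row["onset_sample"]), label=str(row["class"]),
                   trial=int(row["trial"]), position=int(row["position"]))
            for _, row in df.iterrows()]


# ---------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------

def write_json(path, obj) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default))


def write_spectrum_csv(path, spectrum) -> None:
    pd.DataFrame({"freq_hz": spectrum.freqs,
                  "amp": spectrum.amp}).to_csv(path, index=False)


def write_alpha_csv(path, measures) -> None:
    pd.DataFrame({"epoch": np.arange(measures.per_epoch.size),
                  "class": measures.labels,
                  "source": measures.source,
                  "z_mean": measures.per_epoch}).to_csv(path, index=False)


def write_rejection_csv(path, report) -> None:
    rows = [{"epoch": i, "kept": bool(k),
             "reasons": ";".join(sorted(report.reasons.get(i, ())))}
            for i, k in enumerate(report.keep_mask)]
    pd.DataFrame(rows).to_csv(path, index=False)
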