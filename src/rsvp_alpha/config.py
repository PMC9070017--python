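"""Pipeline configuration with study defaults.

Every default here is either the calibration protocol's stated value
(timing, filters, windows, layer grid) or a documented package choice
(see docs/methods.md). The config round-trips losslessly through an
INI-style text file with one section per processing stage.
"""

from __future__ import annotations

import configparser
import dataclasses
import io
from dataclasses import dataclass, field
from typing import Tuple

#: Recording montage (dry-electrode headset, linked-ear reference).
CHANNELS: Tuple[str, ...] = ("FCz", "F7", "Pz", "P4", "PO7", "PO8", "Oz")

#: Occipitoparietal subset averaged into the virtual "POOL" channel.
POSTERIOR_CHANNELS: Tuple[str, ...] = ("Pz", "Oz", "PO7", "PO8")

#: Label of the virtual pooled channel appended by preprocessing.
POOL = "POOL"

#: The 28-character stimulus alphabet: A-Z plus space ("_") and
#: backspace ("<").
ALPHABET: Tuple[str, ...] = tuple("ABCDEFGHIJKLMNOPQRSTUVWXYZ") + ("_", "<")


@dataclass
class FilterConfig:
    low_hz: float = 1.0
    high_hz: float = 45.0
    #: 48 dB/octave asymptotic slope -> Butterworth order 8.
    order: int = 8
    notch_hz: float = 60.0
    notch_q: float = 30.0


@dataclass
class EpochConfig:
    #: Time-frequency epochs: 2.5 s centred on stimulus onset.
    tf_window_ms: Tuple[float, float] = (-1250.0, 1250.0)
    #: ERP epochs.
    erp_window_ms: Tuple[float, float] = (-200.0, 800.0)
    #: Classifier ERP epochs (reference ERP pipeline).
    erp_clf_window_ms: Tuple[float, float] = (0.0, 500.0)
    resample_fs: float = 150.0


@dataclass
class SpectralConfig:
    #: Fraction of each epoch tapered by the Hann edges (total).
    taper_fraction: float = 0.2
    norm_band_hz: Tuple[float, float] = (4.0, 20.0)
    #: "sum" normalises band amplitude to 1; "max" is the alternative
    #: reading of band-relative normalisation.
    norm_mode: str = "sum"
    iaf_band_hz: Tuple[float, float] = (7.5, 12.5)
    harmonic_mask_hz: float = 0.25
    peak_prominence_frac: float = 0.05
    iaf_fallback_hz: float = 10.0


@dataclass
class WaveletConfig:
    f_min_hz: float = 4.0
    f_max_hz: float = 16.0
    n_layers: int = 48
    morlet_c: float = 5.0
    baseline_window_ms: Tuple[float, float] = (-600.0, -100.0)
    response_window_ms: Tuple[float, float] = (300.0, 800.0)


@dataclass
class ArtifactConfig:
    enabled: bool = False
    gradient_uv_per_ms: float = 50.0
    difference_uv: float = 125.0
    difference_window_ms: float = 50.0
    absolute_uv: float = 75.0
    low_activity_uv: float = 0.5
    low_activity_ms: float = 100.0


@dataclass
class ClassifyConfig:
    cv_reps: int = 10
    test_size: float = 0.2
    tune_grid_step_ms: float = 50.0
    tune_baseline_range_ms: Tuple[float, float] = (-1050.0, -600.0)
    tune_response_range_ms: Tuple[float, float] = (150.0, 550.0)
    tune_nested: bool = True
    rda_var_fraction: float = 0.95
    rda_lambda: float = 0.9
    rda_gamma: float = 0.1
    svc_c: float = 1.0


@dataclass
class PipelineConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    epochs: EpochConfig = field(default_factory=EpochConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    artifact: ArtifactConfig = field(default_factory=ArtifactConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    seed: int = 0

    # -- flat-file round trip ------------------------------------------
    def to_text(self) -> str:
        cp = configparser.ConfigParser()
        for sec_name, sec in self._sections():
            cp[sec_name] = {
                f.name: repr(getattr(sec, f.name))
                for f in dataclasses.fields(sec)
            }
        cp["pipeline"] = {"seed": repr(self.seed)}
        buf = io.StringIO()
        cp.write(buf)
        return buf.getvalue()

    def _sections(self):
        return [
            ("filter", self.filter),
            ("epochs", self.epochs),
            ("spectral", self.spectral),
            ("wavelet", self.wavelet),
            ("artifact", self.artifact),
            ("classify", self.classify),
        ]

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        import ast

        cp = configparser.ConfigParser()
        cp.read_string(text)
        cfg = cls()
        for sec_name, sec in cfg._sections():
            if sec_name not in cp:
                continue
            for key, raw in cp[sec_name].items():
                value = ast.literal_eval(raw)
                if isinstance(value, list):
                    value = tuple(value)
                setattr(sec, key, value)
        if "pipeline" in cp and "seed" in cp["pipeline"]:
            cfg.seed = ast.literal_eval(cp["pipeline"]["seed"])
        return cfg

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_text(fh.read())
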