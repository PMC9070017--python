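"""End-to-end calibration analysis: simulate -> preprocess -> spectra /
IAF -> wavelet alpha attenuation -> ERPs -> classifiers.

``run_calibration`` executes the full analysis of one calibration
(simulated or loaded) and returns a result bundle; ``quick_alpha_run``
is the lean path used for repeated-simulation studies, computing only
the pooled-channel alpha attenuation at the IAF layer.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

from . import io as rio
from .artifact import apply_rejection, flag_epochs
from .classify import (CVSpec, ClassifierResult, extract_alpha_features,
                       rda_kde_eval, train_eval, tune_windows)
from .config import POOL, POSTERIOR_CHANNELS, PipelineConfig
from .erp import ErpSummary, erp_summary
from .preprocess import bandpass_notch, epoch, preprocess, resample
from .sim import RawRecording, SimParams, StimulusSchedule, \
    make_schedule, synthesize_recording
from .spectral import amplitude_spectrum, estimate_iaf
from .tf_alpha import (AlphaMeasures, alpha_activity, cwt_scaleogram,
                       layer_frequencies, select_iaf_layer, ztransform)

logger = logging.getLogger(__name__)


@dataclass
class CalibrationResult:
    rate_hz: float
    seed: int
    iaf_hz: float
    iaf_method: str
    alpha: Dict[str, AlphaMeasures]          # source -> measures
    erp: Dict[str, ErpSummary]
    classifiers: Dict[str, ClassifierResult] = field(default_factory=dict)
    tuned_windows: Optional[tuple] = None
    n_epochs: int = 0
    rejection: Optional[object] = None

    def summary(self) -> dict:
        out = {
            "rate_hz": self.rate_hz, "seed": self.seed,
            "iaf_hz": self.iaf_hz, "iaf_method": self.iaf_method,
            "n_epochs": self.n_epochs,
        }
        for src, m in self.alpha.items():
            out[f"attenuation_{src}"] = m.attenuation
            out[f"mwu_p_{src}"] = m.mwu_p
        for src, s in self.erp.items():
            out[f"n200_effect_{src}"] = s.n200_target_effect
            out[f"p300_effect_{src}"] = s.p300_target_effect
        for mid, res in self.classifiers.items():
            out[f"balanced_acc_{mid}"] = res.mean_balanced_acc
        if self.tuned_windows is not None:
            out["tuned_baseline_start_ms"] = self.tuned_windows[0]
            out["tuned_response_start_ms"] = self.tuned_windows[1]
        return out


def simulate_calibration(rate_hz: float, n_trials: int = 100,
                         seq_len: int = 10, seed: int = 0,
                         params: Optional[SimParams] = None,
                         ) -> tuple[StimulusSchedule, RawRecording]:
    """Schedule plus rendered recording for one calibration."""
    schedule = make_schedule(rate_hz, n_trials, seq_len, seed=seed)
    if params is None:
        params = SimParams(seed=seed)
    elif params.seed != seed:
        params = params.replace(seed=seed)
    return schedule, synthesize_recording(schedule, params)


def run_calibration(recording: RawRecording, rate_hz: float,
                    config: Optional[PipelineConfig] = None,
                    seed: int = 0, classifiers: bool = True,
                    tune: bool = False,
                    out_dir: Optional[Path] = None) -> CalibrationResult:
    """Analyse one calibration recording end to end.

    Artifact rejection runs only when ``config.artifact.enabled`` (the
    primary analyses keep all epochs). When ``out_dir`` is given, every
    stage's outputs are written there (CSV/JSON).
    """
    cfg = config or PipelineConfig()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        cfg.save(out / "config.ini")

    pre = preprocess(recording, cfg.filter.low_hz, cfg.filter.high_hz,
                     cfg.filter.notch_hz, order=cfg.filter.order,
                     notch_q=cfg.filter.notch_q,
                     target_fs=cfg.epochs.resample_fs)
    tf_epochs = epoch(pre, cfg.epochs.tf_window_ms)
    if cfg.artifact.enabled:
        report = flag_epochs(tf_epochs,
                             gradient_uv_per_ms=cfg.artifact.gradient_uv_per_ms,
                             difference_uv=cfg.artifact.difference_uv,
                             difference_window_ms=cfg.artifact.difference_window_ms,
                             absolute_uv=cfg.artifact.absolute_uv,
                             low_activity_uv=cfg.artifact.low_activity_uv,
                             low_activity_ms=cfg.artifact.low_activity_ms)
        tf_epochs = apply_rejection(tf_epochs, report)
        if out is not None:
            rio.write_rejection_csv(out / "rejection.csv", report)
    else:
        report = None

    spectrum = amplitude_spectrum(tf_epochs, POOL,
                                  taper_fraction=cfg.spectral.taper_fraction,
                                  norm_band_hz=cfg.spectral.norm_band_hz,
                                  norm_mode=cfg.spectral.norm_mode)
    iaf = estimate_iaf(spectrum, rate_hz,
                       band_hz=cfg.spectral.iaf_band_hz,
                       harmonic_mask_hz=cfg.spectral.harmonic_mask_hz,
                       prominence_frac=cfg.spectral.peak_prominence_frac,
                       fallback_hz=cfg.spectral.iaf_fallback_hz)

    freqs = layer_frequencies(cfg.wavelet.f_min_hz, cfg.wavelet.f_max_hz,
                              cfg.wavelet.n_layers)
    layer = select_iaf_layer(freqs, iaf.iaf_hz)
    scalo = cwt_scaleogram(tf_epochs, layer_freqs=freqs,
                           channels=(POOL, "Pz"), c=cfg.wavelet.morlet_c)
    scalo_z = ztransform(scalo, cfg.wavelet.baseline_window_ms)
    alpha = {src: alpha_activity(scalo_z, layer,
                                 cfg.wavelet.response_window_ms, source=src)
             for src in (POOL, "Pz")}
    del scalo

    erp_epochs = epoch(pre, cfg.epochs.erp_window_ms)
    erp = {src: erp_summary(erp_epochs, src) for src in (POOL, "Pz")}

    result = CalibrationResult(rate_hz=rate_hz, seed=seed,
                               iaf_hz=iaf.iaf_hz, iaf_method=iaf.method,
                               alpha=alpha, erp=erp,
                               n_epochs=tf_epochs.n_epochs,
                               rejection=report)

    if classifiers:
        cv = CVSpec(n_reps=cfg.classify.cv_reps,
                    test_size=cfg.classify.test_size)
        mag4 = cwt_scaleogram(tf_epochs, layer_freqs=freqs[[layer]],
                              channels=POSTERIOR_CHANNELS,
                              c=cfg.wavelet.morlet_c)
        z4 = ztransform(mag4, cfg.wavelet.baseline_window_ms)
        feats = extract_alpha_features(z4, 0,
                                       cfg.wavelet.response_window_ms)
        for mid in ("logreg_l2", "svc", "tangent_space", "uniform_random"):
            result.classifiers[mid] = train_eval(
                feats, mid, cv=cv, seed=seed, svc_c=cfg.classify.svc_c)

        if tune:
            grid = tune_windows(
                mag4, grid_step_ms=cfg.classify.tune_grid_step_ms,
                cv=cv, seed=seed, nested=cfg.classify.tune_nested,
                baseline_range_ms=cfg.classify.tune_baseline_range_ms,
                response_range_ms=cfg.classify.tune_response_range_ms)
            result.tuned_windows = grid.best

        erp_pre = bandpass_notch(recording, 2.0, 45.0, cfg.filter.notch_hz,
                                 order=cfg.filter.order,
                                 notch_q=cfg.filter.notch_q)
        erp_pre = resample(erp_pre, cfg.epochs.resample_fs)
        erp_clf_epochs = epoch(erp_pre, cfg.epochs.erp_clf_window_ms)
        result.classifiers["rda_kde"] = rda_kde_eval(
            erp_clf_epochs, cv=cv, seed=seed,
            var_fraction=cfg.classify.rda_var_fraction,
            lam=cfg.classify.rda_lambda, gamma=cfg.classify.rda_gamma)

    if out is not None:
        rio.write_spectrum_csv(out / "spectrum.csv", spectrum)
        rio.write_json(out / "iaf.json",
                       {"iaf_hz": iaf.iaf_hz, "method": iaf.method,
                        "excluded_freqs": iaf.excluded_freqs})
        for src, m in alpha.items():
            rio.write_alpha_csv(out / f"alpha_{src}.csv", m)
        rio.write_json(out / "attenuation.json",
                       {src: {"attenuation": m.attenuation,
                              "mwu_p": m.mwu_p,
                              "class_medians": m.class_medians}
                        for src, m in alpha.items()})
        rio.write_json(out / "erp.json",
                       {src: dataclasses.asdict(s) for src, s in erp.items()})
        if result.classifiers:
            rio.write_json(out / "classifiers.json",
                           {mid: {"per_split": r.per_split_balanced_acc,
                                  "mean": r.mean_balanced_acc,
                                  "cv": r.cv_spec}
                            for mid, r in result.classifiers.items()})
        rio.write_json(out / "summary.json", result.summary())
    return result


def quick_alpha_run(rate_hz: float, seed: int,
                    params: Optional[SimParams] = None,
                    n_trials: int = 100,
                    config: Optional[PipelineConfig] = None,
                    source: str = POOL) -> AlphaMeasures:
    """Lean repeated-simulation path: pooled-channel alpha attenuation
    at the IAF layer only (no ERP analysis, no classifiers)."""
    cfg = config or PipelineConfig()
    schedule, rec = simulate_calibration(rate_hz, n_trials, seed=seed,
                                         params=params)
    pre = preprocess(rec, cfg.filter.low_hz, cfg.filter.high_hz,
                     cfg.filter.notch_hz, order=cfg.filter.order,
                     target_fs=cfg.epochs.resample_fs)
    tf_epochs = epoch(pre, cfg.epochs.tf_window_ms)
    spectrum = amplitude_spectrum(tf_epochs, source)
    iaf = estimate_iaf(spectrum, rate_hz)
    freqs = layer_frequencies()
    layer = select_iaf_layer(freqs, iaf.iaf_hz)
    scalo = cwt_scaleogram(tf_epochs, layer_freqs=freqs[[layer]],
                           channels=(source,))
    scalo_z = ztransform(scalo, cfg.wavelet.baseline_window_ms)
    return alpha_activity(scalo_z, 0, cfg.wavelet.response_window_ms,
                          source=source)
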