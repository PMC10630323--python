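"""End-to-end runners binding the modules into the two pipelines.

Pipeline 1 (vitals estimation): frames/signal -> PPG extraction -> wavelet
filtering -> segmentation -> network prediction (or caption querying) ->
per-window vitals report.

Pipeline 2 (ECG synthesis): PPG -> pulse-peak detection -> envelope
detrending -> cycle-wise DCT regression -> synthetic single-lead ECG, with
waveform metrics when a reference ECG is supplied.

Configurations are YAML files validated against pydantic models; demo mode
substitutes the synthetic generator so no input data is ever required.
Every run writes a manifest (config hash, seed, package version) next to its
outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .core import Signal
from .metrics import dirichlet_distance, mae_sae, peak_error_table, pearson
from .p2e import P2eSpec, fit_p2e, pair_cycles, reconstruct_ecg
from .peaks import ECG_PROFILE, PPG_PROFILE, detect_valleys, terma_detect
from .preprocess import WaveletSpec, detrend, segment, wavelet_filter
from .siggen import SimConfig, generate_recording
from .vitals_models import ModelSpec, TrainSpec, VitalsRegressor
from .vppg_io import FrameStack, Roi, extract_ppg, read_signal, write_signal

__all__ = ["PipelineConfig", "run_vitals_pipeline", "run_p2e_pipeline"]


class SimSection(BaseModel):
    fs: float = 125.0
    duration: float = 60.0
    hr: float = 75.0
    rr: float = 15.0
    spo2: float = 97.0
    ptt_lag: float = 200.0
    noise_sd: float = 0.02
    drift_amp: float = 0.3

    def to_config(self, seed: int) -> SimConfig:
        return SimConfig(seed=seed, **self.model_dump())


class PipelineConfig(BaseModel):
    """Validated run configuration for both pipelines."""

    demo: bool = True
    input_signal: str | None = None
    frames_dir: str | None = None
    video: str | None = None
    fps: float | None = None
    roi_fraction: float = 0.5
    seed: int = 0
    out_dir: str = "runs"
    # vitals stage
    w_s: float = 10.0
    vitals: list[str] = Field(default_factory=lambda: ["hr"])
    model: str = "mt_net"
    max_epochs: int = 100
    apply_wavelet: bool = True
    # p2e stage
    p2e_config: str = "ffnn"
    sim: SimSection = Field(default_factory=SimSection)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})


def _write_manifest(out: Path, cfg: PipelineConfig) -> None:
    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    manifest = {
        "config": cfg.model_dump(),
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": cfg.seed,
        "ppgvitals_version": __version__,
        "numpy_version": np.__version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _load_input(cfg: PipelineConfig) -> tuple[Signal, pd.DataFrame | None, Signal | None]:
    """Returns (ppg signal, labels or None, reference ecg or None)."""
    if cfg.demo:
        rec = generate_recording(cfg.sim.to_config(cfg.seed))
        return rec.ppg, rec.labels, rec.ecg
    if cfg.input_signal:
        return read_signal(cfg.input_signal), None, None
    if cfg.frames_dir:
        if cfg.fps is None:
            raise ValueError("fps is required with a frame directory")
        stack = FrameStack.from_directory(cfg.frames_dir, cfg.fps)
    elif cfg.video:
        stack = FrameStack.from_video(cfg.video, cfg.fps)
    else:
        raise ValueError("no input: set demo, input_signal, frames_dir or video")
    return extract_ppg(stack, Roi(center_fraction=cfg.roi_fraction)), None, None


def run_vitals_pipeline(cfg: PipelineConfig) -> dict:
    """Extract -> filter -> segment -> train/predict -> report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        ppg, labels, _ = _load_input(cfg)
    except Exception as err:  # noqa: BLE001
        raise RuntimeError(f"[input stage] {err}") from err

    x = ppg.channel("green") if ppg.n_channels >= 2 else ppg
    if cfg.apply_wavelet:
        x = wavelet_filter(x, WaveletSpec())
    if labels is None:
        raise RuntimeError(
            "[segment stage] training labels are required; use demo mode or "
            "provide a labelled dataset"
        )
    ds = segment(x, labels[cfg.vitals], w_s=cfg.w_s, subject=0)
    mu = ds.segments.mean(axis=1, keepdims=True)
    sd = ds.segments.std(axis=1, keepdims=True) + 1e-9
    ds.segments = (ds.segments - mu) / sd

    spec = ModelSpec(name=cfg.model, n_outputs=ds.n_vitals, conv_filters=(8, 16, 32))
    tr = TrainSpec(max_epochs=cfg.max_epochs, scale_labels=True, seed=cfg.seed)
    results = VitalsRegressor(ds, spec, tr).fit(seed=cfg.seed)

    pred = results.predictions_frame(ds.segments)
    pred.insert(0, "window_start_s", np.arange(len(pred)))
    pred.to_csv(out / "predictions.csv", index=False)

    report: dict = {"n_segments": len(ds), "vitals": list(cfg.vitals)}
    for j, name in enumerate(results.vital_names):
        mae, sae = mae_sae(ds.labels[:, j], pred[name].to_numpy())
        report[f"mae_{name}"] = mae
        report[f"sae_{name}"] = sae
    (out / "vitals_report.json").write_text(json.dumps(report, indent=2))
    _write_manifest(out, cfg)
    return {"report": report, "predictions": pred, "results": results}


def run_p2e_pipeline(cfg: PipelineConfig) -> dict:
    """Detrend -> pulse peaks -> cycle regression -> synthetic ECG + metrics."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        ppg, _, ecg_ref = _load_input(cfg)
    except Exception as err:  # noqa: BLE001
        raise RuntimeError(f"[input stage] {err}") from err

    x = ppg.channel("green") if ppg.n_channels >= 2 else ppg
    try:
        p_peaks = terma_detect(x, PPG_PROFILE)
        p_valleys = detect_valleys(x, p_peaks)
        ppg_d = detrend(x, p_peaks, p_valleys)
    except ValueError as err:
        raise RuntimeError(f"[detrend stage] {err}") from err

    if ecg_ref is None:
        raise RuntimeError(
            "[fit stage] training requires a simultaneous reference ECG; "
            "use demo mode or fit on a prepared cycle bank"
        )
    r_peaks = terma_detect(ecg_ref, ECG_PROFILE)
    r_valleys = detect_valleys(ecg_ref, r_peaks)
    ecg_d = detrend(ecg_ref, r_peaks, r_valleys)
    pairs = pair_cycles(ppg_d, ecg_d, p_peaks, r_peaks)
    spec = P2eSpec(config=cfg.p2e_config, max_epochs=min(300, 1000))
    results = fit_p2e(pairs, spec, seed=cfg.seed)

    ecg_synth, offset = reconstruct_ecg(ppg_d, p_peaks, results)
    write_signal(ecg_synth, out / "ecg_synth.csv")

    report: dict = {
        "n_cycles": len(pairs),
        "config": cfg.p2e_config,
        "offset_samples": offset,
    }
    ev = results.evaluate(pairs)
    report["p_corr"] = float(ev["p_corr"].mean())
    report["mae"] = float(ev["mae"].mean())
    report["l_dir"] = float(ev["l_dir"].mean())
    # fiducial windows are defined in ms, so use the effective sampling rate
    # of the fixed-length resampled cycles
    eff_fs = x.fs * results.spec.L / float(np.median([p.native_len for p in pairs]))
    table = peak_error_table(
        {0: [(p.ecg, results.predict_cycle(p.ppg)) for p in pairs]}, fs=eff_fs
    )
    report["peak_errors"] = table[["MMAE", "MSAE"]].round(6).to_dict()
    (out / "p2e_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    _write_manifest(out, cfg)
    return {"report": report, "ecg_synth": ecg_synth, "results": results, "pairs": pairs}
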