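"""Seeded generator of paired synthetic PPG / ECG / video fixtures.

The generator emulates the structure of simultaneously recorded fingertip
camera-PPG and single-lead ECG: aligned cardiac cycles in which the ECG R-peak
precedes the PPG pulse peak by a pulse-transit lag, respiratory baseline
wander and amplitude modulation at the breathing frequency, colour channels
whose AC/DC ratios encode SpO2 through a fixed ratio-of-ratios convention,
1 Hz label streams, and pixel-intensity frame stacks whose spatial mean
reproduces the PPG.

ECG morphology follows the classical five-Gaussian parameterization: one
Gaussian bump per wave (P, Q, R, S, T) placed at fixed angular positions
within the cardiac cycle, amplitudes scaled to a unit R-peak.

The SpO2 convention is ``SpO2 = 110 - 25 * R`` where ``R`` is the
ratio-of-ratios ``(AC_red / DC_red) / (AC_green / DC_green)``; the generator
inverts it to set the red-channel pulsatile amplitude, so estimators can be
tested for recovery of a known encoding.

All randomness flows from ``SimConfig.seed``: identical configs produce
bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import PeakSet, Signal
from .vppg_io import FrameStack

__all__ = [
    "SimConfig",
    "PairedRecording",
    "gen_ecg",
    "gen_ppg",
    "gen_frames",
    "gen_caption_corpus",
    "generate_recording",
    "ECG_MORPHOLOGY",
]

# (wave, angular position in rad, amplitude relative to R, width in rad)
ECG_MORPHOLOGY = {
    "P": (np.deg2rad(-70.0), 1.2 / 30.0, 0.25),
    "Q": (np.deg2rad(-15.0), -5.0 / 30.0, 0.10),
    "R": (0.0, 1.0, 0.10),
    "S": (np.deg2rad(15.0), -7.5 / 30.0, 0.10),
    "T": (np.deg2rad(100.0), 0.75 / 30.0, 0.40),
}

# Channel DC levels (8-bit intensity scale) and green perfusion (AC/DC)
_DC = {"red": 180.0, "green": 120.0, "blue": 60.0}
_GREEN_PERFUSION = 0.05


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic recording.

    noise_sd and drift_amp are relative to each signal's pulsatile (AC)
    amplitude, so one value means the same signal-to-noise ratio for the ECG
    (unit R-peak) and each PPG colour channel.  rsa_amp is the fractional
    respiratory-sinus modulation of the instantaneous heart rate (0 disables
    it, giving perfectly regular R-R intervals).
    """

    fs: float = 125.0
    duration: float = 60.0
    hr: float = 75.0
    rr: float = 15.0
    spo2: float = 97.0
    ptt_lag: float = 200.0  # ms between R-peak and PPG pulse peak
    noise_sd: float = 0.02
    drift_amp: float = 0.3
    rsa_amp: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not 30 <= self.hr <= 220:
            raise ValueError(f"hr={self.hr} outside the physiological range [30, 220]")
        if not 5 <= self.rr <= 60:
            raise ValueError(f"rr={self.rr} outside the physiological range [5, 60]")
        if not 70 <= self.spo2 <= 100:
            raise ValueError(f"spo2={self.spo2} outside the range [70, 100]")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class PairedRecording:
    """One synthetic session: colour PPG, single-lead ECG, 1 Hz labels and
    ground-truth fiducials."""

    ppg: Signal
    ecg: Signal
    labels: pd.DataFrame  # columns hr, spo2, rr at 1 Hz
    r_peaks: PeakSet
    pulse_peaks: PeakSet
    config: SimConfig = field(repr=False, default=None)


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    # independent substreams per signal kind, all derived from cfg.seed
    return np.random.default_rng([int(cfg.seed) % (2**31), stream])


def _instantaneous_hr(cfg: SimConfig, t: float) -> float:
    return cfg.hr * (1.0 + cfg.rsa_amp * np.sin(2 * np.pi * cfg.rr / 60.0 * t))


def _beat_starts(cfg: SimConfig, n: int) -> list[tuple[int, int]]:
    """Sequential (start, period-in-samples) pairs covering n samples."""
    beats = []
    start = 0
    while start < n:
        hr_t = _instantaneous_hr(cfg, start / cfg.fs)
        period = max(2, int(round(cfg.fs * 60.0 / hr_t)))
        beats.append((start, period))
        start += period
    return beats


def _ecg_cycle(period: int) -> np.ndarray:
    theta = -np.pi + 2 * np.pi * np.arange(period) / period
    wave = np.zeros(period)
    for _, (pos, amp, width) in ECG_MORPHOLOGY.items():
        wave += amp * np.exp(-((theta - pos) ** 2) / (2 * width**2))
    return wave


def gen_ecg(cfg: SimConfig) -> tuple[Signal, PeakSet]:
    """Quasi-periodic five-Gaussian ECG with exact R-peak indices.

    Returns the single-lead signal (unit R-peak amplitude before noise) and
    the ground-truth R-peak sample positions.
    """
    n = int(round(cfg.duration * cfg.fs))
    out = np.zeros(n)
    r_indices = []
    for start, period in _beat_starts(cfg, n):
        cycle = _ecg_cycle(period)
        stop = min(start + period, n)
        out[start:stop] = cycle[: stop - start]
        r = start + int(round(period / 2))
        if r < n:
            r_indices.append(r)
    if cfg.noise_sd > 0:
        out = out + _rng(cfg, 1).normal(0.0, cfg.noise_sd, size=n)
    return Signal(out, cfg.fs, ("ecg",)), PeakSet(np.array(r_indices), "peak")


def _gaussian_pulse(n: int, centers: np.ndarray, widths: np.ndarray, amps: np.ndarray) -> np.ndarray:
    """Sum of Gaussian bumps on the sample grid (support limited to 4 sigma)."""
    out = np.zeros(n)
    for c, w, a in zip(centers, widths, amps):
        lo = max(0, int(np.floor(c - 4 * w)))
        hi = min(n, int(np.ceil(c + 4 * w)) + 1)
        if hi <= lo:
            continue
        j = np.arange(lo, hi)
        out[j] += a * np.exp(-((j - c) ** 2) / (2 * w**2))
    return out


def gen_ppg(cfg: SimConfig, r_peaks: PeakSet) -> tuple[Signal, PeakSet]:
    """Three-channel camera PPG aligned to the given R-peaks.

    Per beat, a systolic Gaussian wave delayed by the pulse-transit lag plus a
    smaller dicrotic wave; channel AC amplitudes encode SpO2 via the
    ratio-of-ratios convention; respiratory drift and amplitude modulation at
    the breathing frequency; pulse-peak indices are returned exactly.
    """
    if len(r_peaks) == 0:
        raise ValueError("gen_ppg requires at least one R-peak")
    n = int(round(cfg.duration * cfg.fs))
    lag = int(round(cfg.ptt_lag * cfg.fs / 1000.0))
    r = r_peaks.indices
    periods = np.diff(r)
    periods = np.append(periods, periods[-1] if len(periods) else int(cfg.fs * 60 / cfg.hr))

    sys_centers = r + lag
    keep = sys_centers < n
    sys_centers, periods_k = sys_centers[keep], periods[keep]
    sys_w = 0.13 * periods_k
    dic_centers = sys_centers + 0.30 * periods_k
    dic_w = 0.18 * periods_k

    pulse = _gaussian_pulse(n, sys_centers, sys_w, np.ones(len(sys_centers)))
    pulse += _gaussian_pulse(n, dic_centers, dic_w, 0.35 * np.ones(len(dic_centers)))

    t = np.arange(n) / cfg.fs
    f_resp = cfg.rr / 60.0
    am = 1.0 + 2.0 * cfg.drift_amp * 0.1 * np.sin(2 * np.pi * f_resp * t)
    drift = np.sin(2 * np.pi * f_resp * t)

    ratio = (110.0 - cfg.spo2) / 25.0  # ratio-of-ratios target
    ac = {
        "red": ratio * _GREEN_PERFUSION * _DC["red"],
        "green": _GREEN_PERFUSION * _DC["green"],
        "blue": 0.8 * _GREEN_PERFUSION * _DC["blue"],
    }
    rng = _rng(cfg, 2)
    channels = []
    for name in ("red", "green", "blue"):
        x = _DC[name] + ac[name] * pulse * am + cfg.drift_amp * ac[name] * drift
        if cfg.noise_sd > 0:
            x = x + rng.normal(0.0, cfg.noise_sd * ac[name], size=n)
        channels.append(x)
    data = np.stack(channels, axis=1)
    return Signal(data, cfg.fs, ("red", "green", "blue")), PeakSet(sys_centers, "peak")


def gen_frames(
    ppg: Signal,
    height: int = 16,
    width: int = 16,
    spatial_sd: float = 2.0,
    quantize: bool = True,
    seed: int = 0,
) -> FrameStack:
    """Render a PPG as a stack of frames whose ROI mean recovers the signal.

    Every pixel of frame ``t`` holds the channel value at sample ``t`` plus
    zero-mean spatial noise; intensities are clamped to [0, 255] (with a
    warning) and quantized to 8 bits unless ``quantize`` is off.
    """
    data = ppg.as_2d()  # (n, ch)
    n, ch = data.shape
    frames = np.broadcast_to(data[:, None, None, :], (n, height, width, ch)).astype(float)
    if spatial_sd > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, spatial_sd, size=frames.shape)
    else:
        frames = frames.copy()
    if quantize:
        if frames.min() < -0.5 or frames.max() > 255.5:
            warnings.warn("frame intensities clamped to the 8-bit range", stacklevel=2)
        frames = np.clip(np.round(frames), 0, 255).astype(np.uint8)
    return FrameStack(frames, fps=ppg.fs)


def generate_recording(cfg: SimConfig) -> PairedRecording:
    """Full paired session: ECG + colour PPG + 1 Hz labels + truth fiducials."""
    ecg, r_peaks = gen_ecg(cfg)
    ppg, pulse_peaks = gen_ppg(cfg, r_peaks)
    seconds = np.arange(int(np.floor(cfg.duration)))
    labels = pd.DataFrame(
        {
            "hr": [_instantaneous_hr(cfg, float(s)) for s in seconds],
            "spo2": cfg.spo2,
            "rr": cfg.rr,
        },
        index=pd.Index(seconds, name="second"),
    )
    return PairedRecording(ppg, ecg, labels, r_peaks, pulse_peaks, cfg)


def gen_caption_corpus(
    n: int,
    hr_range: tuple[float, float] = (50.0, 150.0),
    spo2_range: tuple[float, float] = (85.0, 100.0),
    rr_range: tuple[float, float] = (8.0, 30.0),
    seed: int = 0,
    w_s: float = 10.0,
    fs: float = 125.0,
    include_bp: bool = False,
    noise_sd: float = 0.02,
) -> list[dict]:
    """Paired (PPG segment, caption, labels) records for contrastive training.

    Each record holds a ``w_s``-second standardized green-channel PPG segment,
    a caption templated from its true vitals (optionally with SBP/DBP fields
    mimicking blood-pressure-annotated corpora) and the numeric labels.
    """
    from .vitals_clip import make_caption

    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    records = []
    n_seg = int(round(w_s * fs))
    for i in range(n):
        hr = float(rng.uniform(*hr_range))
        spo2 = float(rng.uniform(*spo2_range))
        rr = float(rng.uniform(*rr_range))
        cfg = SimConfig(
            fs=fs,
            duration=w_s + 2.0,
            hr=hr,
            spo2=spo2,
            rr=rr,
            noise_sd=noise_sd,
            seed=int(rng.integers(2**31)),
        )
        rec = generate_recording(cfg)
        seg = rec.ppg.data[:n_seg, 1]  # green channel
        seg = (seg - seg.mean()) / (seg.std() + 1e-12)
        labels = {"hr": round(hr, 1), "spo2": round(spo2, 1), "rr": round(rr, 1)}
        if include_bp:
            labels["sbp"] = round(float(rng.uniform(95, 160)), 1)
            labels["dbp"] = round(float(rng.uniform(55, 100)), 1)
        records.append(
            {"segment": seg, "caption": make_caption(labels).text, "labels": labels}
        )
    return records


def vary(cfg: SimConfig, **kwargs) -> SimConfig:
    """Convenience: a copy of cfg with the given fields replaced."""
    return replace(cfg, **kwargs)
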