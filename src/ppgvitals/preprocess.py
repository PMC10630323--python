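"""Signal conditioning: wavelet filtering, envelope detrending, segmentation.

The wavelet rule removes the slow baseline (respiration, ambient light) held
in the level-5 approximation band and the high-frequency noise / motion
artifacts held in the first two detail bands, keeping everything else.

Detrending normalizes each sample between a lower envelope through the
valleys and an upper envelope through the peaks (natural cubic splines), so
the waveform ends up in [0, 1], then subtracts 0.5 to center it at zero.
Beat-to-beat amplitude and baseline variation are removed, which is the scale
on which cycle-wise PPG-to-ECG regression operates.

Segmentation slides fixed-width windows over the signal at a 1 s stride and
averages the per-second vitals labels each window spans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy.interpolate import CubicSpline

from .core import PeakSet, Signal

__all__ = ["WaveletSpec", "SegmentDataset", "wavelet_filter", "detrend", "segment"]


@dataclass(frozen=True)
class WaveletSpec:
    family: str = "db4"
    levels: int = 5
    drop_approx: bool = True
    drop_detail_levels: frozenset[int] = frozenset({1, 2})

    def __post_init__(self) -> None:
        if self.drop_detail_levels and self.levels < max(self.drop_detail_levels):
            raise ValueError("levels must cover every dropped detail level")


def _filter_channel(x: np.ndarray, spec: WaveletSpec) -> np.ndarray:
    coeffs = pywt.wavedec(x, spec.family, level=spec.levels, mode="symmetric")
    # coeffs = [approx, detail_L, ..., detail_1]
    if spec.drop_approx:
        coeffs[0] = np.zeros_like(coeffs[0])
    for lvl in spec.drop_detail_levels:
        coeffs[-lvl] = np.zeros_like(coeffs[-lvl])
    out = pywt.waverec(coeffs, spec.family, mode="symmetric")
    return out[: len(x)]


def wavelet_filter(x: Signal, spec: WaveletSpec | None = None) -> Signal:
    """Five-level decomposition; zero the approximation and detail levels 1-2;
    reconstruct.  Linear, length-preserving."""
    spec = spec or WaveletSpec()
    n = x.n_samples
    if n < 2**spec.levels:
        raise ValueError(
            f"signal too short for a {spec.levels}-level decomposition "
            f"({n} < {2**spec.levels} samples)"
        )
    if not np.all(np.isfinite(x.data)):
        raise ValueError("signal contains non-finite samples")
    if x.data.ndim == 1:
        data = _filter_channel(x.data, spec)
    else:
        data = np.stack(
            [_filter_channel(x.data[:, c], spec) for c in range(x.n_channels)], axis=1
        )
    return Signal(data, x.fs, x.channel_names)


def _envelope(indices: np.ndarray, values: np.ndarray, n: int) -> np.ndarray:
    """Natural cubic spline through (index, value); clamped to the nearest
    fiducial value outside the outermost fiducials."""
    if len(indices) < 2:
        raise ValueError("need at least 2 fiducials per envelope")
    spline = CubicSpline(indices, values, bc_type="natural")
    grid = np.arange(n, dtype=float)
    env = spline(np.clip(grid, indices[0], indices[-1]))
    return env


def detrend(
    x: Signal,
    peaks: PeakSet,
    valleys: PeakSet,
    overshoot_warn: float = 0.05,
) -> Signal:
    """Envelope-normalize a single-channel signal to [-0.5, 0.5].

    ``y = (x - lower) / (upper - lower) - 0.5`` with the upper envelope
    through the peaks and the lower through the valleys.  Peak samples map to
    +0.5 and valley samples to -0.5 exactly; spline overshoot beyond
    ``overshoot_warn`` raises a warning flag in the returned signal's range.
    """
    if x.data.ndim != 1:
        raise ValueError("detrend expects a single-channel signal")
    if len(peaks) < 2 or len(valleys) < 2:
        raise ValueError("detrend needs at least 2 peaks and 2 valleys")
    n = x.n_samples
    upper = _envelope(peaks.indices, x.data[peaks.indices], n)
    lower = _envelope(valleys.indices, x.data[valleys.indices], n)
    span = upper - lower
    bad = np.nonzero(span <= 0)[0]
    if bad.size:
        raise ValueError(
            f"degenerate envelope: upper <= lower first at sample {bad[0]}"
        )
    y = (x.data - lower) / span - 0.5
    lo = int(min(peaks.indices[0], valleys.indices[0]))
    hi = int(max(peaks.indices[-1], valleys.indices[-1]))
    inner = y[lo : hi + 1]
    if inner.size and (inner.max() > 0.5 + overshoot_warn or inner.min() < -0.5 - overshoot_warn):
        import warnings

        warnings.warn(
            "detrended signal overshoots [-0.5, 0.5] by more than "
            f"{overshoot_warn}; check fiducials", stacklevel=2,
        )
    return Signal(y, x.fs, x.channel_names)


@dataclass
class SegmentDataset:
    """Fixed-width windows with window-averaged vitals labels.

    segments: (N, w_s*F_s, ch); labels: (N, N_v); subjects: optional (N,)
    provenance ids used by subject-disjoint splits.
    """

    segments: np.ndarray
    labels: np.ndarray
    w_s: float
    fs: float
    vital_names: tuple[str, ...]
    subjects: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, float)
        self.labels = np.asarray(self.labels, float)
        if self.segments.ndim == 2:
            self.segments = self.segments[:, :, None]
        if self.labels.ndim == 1:
            self.labels = self.labels[:, None]
        if len(self.segments) != len(self.labels):
            raise ValueError("label count must equal segment count")
        if self.subjects is not None and len(self.subjects) != len(self.segments):
            raise ValueError("subject ids must match segment count")

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def n_vitals(self) -> int:
        return self.labels.shape[1]

    @property
    def n_channels(self) -> int:
        return self.segments.shape[2]

    def select_vitals(self, names: list[str]) -> "SegmentDataset":
        idx = [self.vital_names.index(v) for v in names]
        return SegmentDataset(
            self.segments, self.labels[:, idx], self.w_s, self.fs, tuple(names), self.subjects
        )

    def concat(self, other: "SegmentDataset") -> "SegmentDataset":
        if self.vital_names != other.vital_names or self.w_s != other.w_s:
            raise ValueError("incompatible datasets")
        subj = None
        if self.subjects is not None and other.subjects is not None:
            subj = np.concatenate([self.subjects, other.subjects])
        return SegmentDataset(
            np.concatenate([self.segments, other.segments]),
            np.concatenate([self.labels, other.labels]),
            self.w_s,
            self.fs,
            self.vital_names,
            subj,
        )

    def save(self, path) -> None:
        """Persist as a compressed archive (arrays + metadata)."""
        np.savez_compressed(
            path,
            segments=self.segments,
            labels=self.labels,
            subjects=self.subjects if self.subjects is not None else np.array([]),
            meta=np.array(
                [str(self.w_s), str(self.fs), ",".join(self.vital_names)], dtype=object
            ),
        )

    @classmethod
    def load(cls, path) -> "SegmentDataset":
        z = np.load(path, allow_pickle=True)
        w_s, fs, names = z["meta"]
        subjects = z["subjects"] if z["subjects"].size else None
        return cls(z["segments"], z["labels"], float(w_s), float(fs), tuple(names.split(",")), subjects)


def segment(
    x: Signal,
    labels: pd.DataFrame,
    w_s: float,
    stride: float = 1.0,
    subject: object | None = None,
) -> SegmentDataset:
    """Sliding-window segmentation with window-averaged labels.

    Windows start every ``stride`` seconds; each window's label is the mean of
    the per-second labels it spans.  For an integer-second signal of duration
    T the window count is ``floor(T - w_s) + 1`` at a 1 s stride.
    """
    n_win = int(round(w_s * x.fs))
    if abs(w_s * x.fs - n_win) > 1e-9:
        raise ValueError("w_s * fs must be an integral number of samples")
    n_stride = int(round(stride * x.fs))
    T = x.duration
    if w_s > T:
        raise ValueError(f"window {w_s} s exceeds signal duration {T} s")
    if len(labels) < int(np.floor(T)):
        raise ValueError("label stream does not cover the signal duration")
    data = x.as_2d()
    segs, labs, subs = [], [], []
    lab = labels.to_numpy(float)
    start = 0
    while start + n_win <= x.n_samples:
        sec0 = int(round(start / x.fs))
        sec1 = sec0 + int(round(w_s))
        if sec1 > len(lab):
            break
        segs.append(data[start : start + n_win])
        labs.append(lab[sec0:sec1].mean(axis=0))
        subs.append(subject)
        start += n_stride
    return SegmentDataset(
        np.stack(segs),
        np.stack(labs),
        w_s,
        x.fs,
        tuple(labels.columns),
        np.array(subs) if subject is not None else None,
    )
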