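"""Frame-stack input and columnar signal I/O.

Camera PPG starts life as a stack of video frames; :func:`extract_ppg`
collapses each frame to one sample per colour channel by averaging the pixels
inside a region of interest (ROI).  Signals travel on disk as plain CSV
(columns ``time`` plus one per channel) with a JSON sidecar holding the
sampling rate.

Conventions: pixel coordinates are 0-based, ROI rectangles are half-open
``[row0, row1) x [col0, col1)``, channel order is red, green, blue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Signal

__all__ = ["FrameStack", "Roi", "extract_ppg", "read_signal", "write_signal"]


@dataclass
class FrameStack:
    """A sequence of equally shaped intensity frames at a fixed frame rate.

    ``frames`` has shape ``(n, H, W, ch)`` with integer (or float, for
    unquantized synthetic stacks) intensities; ``fps`` is frames per second.
    """

    frames: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 3:  # single channel without axis
            self.frames = self.frames[..., None]
        if self.frames.ndim != 4:
            raise ValueError("frames must have shape (n, H, W, ch)")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:3]

    @classmethod
    def from_directory(cls, path: str | Path, fps: float) -> "FrameStack":
        """Load a stack from a directory of per-frame images (sorted by name)."""
        import imageio.v3 as iio

        files = sorted(Path(path).iterdir())
        files = [f for f in files if f.suffix.lower() in (".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg")]
        if not files:
            raise FileNotFoundError(f"no image frames found in {path}")
        frames = np.stack([iio.imread(f) for f in files])
        return cls(frames, fps)

    @classmethod
    def from_video(cls, path: str | Path, fps: float | None = None) -> "FrameStack":
        """Thin adapter around imageio for MP4/AVI containers."""
        import imageio.v3 as iio

        frames = iio.imread(path, plugin="pyav")
        if fps is None:
            meta = iio.immeta(path, plugin="pyav")
            fps = float(meta.get("fps", 0.0))
            if fps <= 0:
                raise ValueError("frame rate not found in container; pass fps explicitly")
        return cls(np.asarray(frames), fps)


@dataclass
class Roi:
    """Region of interest: a centered fraction of the frame, or an explicit
    half-open rectangle ``(row0, row1, col0, col1)``."""

    center_fraction: float | None = 0.5
    rect: tuple[int, int, int, int] | None = None

    def bounds(self, height: int, width: int) -> tuple[int, int, int, int]:
        if self.rect is not None:
            r0, r1, c0, c1 = self.rect
            r0, c0 = max(r0, 0), max(c0, 0)
            r1, c1 = min(r1, height), min(c1, width)
        else:
            f = float(self.center_fraction)
            if not 0 < f <= 1:
                raise ValueError("center_fraction must lie in (0, 1]")
            rh, cw = max(1, round(height * f)), max(1, round(width * f))
            r0 = (height - rh) // 2
            c0 = (width - cw) // 2
            r1, c1 = r0 + rh, c0 + cw
        if r1 <= r0 or c1 <= c0:
            raise ValueError("ROI does not intersect the frame")
        return r0, r1, c0, c1


def extract_ppg(stack: FrameStack, roi: Roi | None = None) -> Signal:
    """Pixel-average each frame inside the ROI to one sample per channel.

    Returns a Signal of length ``stack.n_frames`` with ``fs = stack.fps``.
    """
    if stack.n_frames < 2:
        raise ValueError("need at least 2 frames to form a time series")
    roi = roi or Roi()
    h, w = stack.frame_shape
    r0, r1, c0, c1 = roi.bounds(h, w)
    patch = stack.frames[:, r0:r1, c0:c1, :].astype(float)
    data = patch.mean(axis=(1, 2))  # (n, ch)
    names = ("red", "green", "blue") if data.shape[1] == 3 else None
    if data.shape[1] == 1:
        data = data[:, 0]
        names = None
    return Signal(data, fs=stack.fps, channel_names=names)


_DEFAULT_NAMES = {1: ("value",), 2: ("red", "green"), 3: ("red", "green", "blue")}


def write_signal(signal: Signal, path: str | Path) -> None:
    """Write a signal as CSV (time + channels) with a JSON ``fs`` sidecar."""
    path = Path(path)
    data = signal.as_2d()
    names = signal.channel_names
    if names == tuple(f"ch{i}" for i in range(signal.n_channels)):
        names = _DEFAULT_NAMES.get(signal.n_channels, names)
    df = pd.DataFrame({"time": signal.times})
    for i, name in enumerate(names):
        df[name] = data[:, i]
    df.to_csv(path, index=False, float_format="%.12g")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"fs": signal.fs}))


def read_signal(path: str | Path) -> Signal:
    """Read a CSV signal written by :func:`write_signal`.

    The sampling rate comes from the sidecar when present; otherwise it is
    inferred from a uniform time column.  Non-uniform timestamps (beyond 1e-6
    relative jitter) and missing values are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "time" not in df.columns or len(df.columns) < 2:
        raise ValueError(f"{path}: expected a 'time' column plus channel columns")
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values in signal file")
    t = df["time"].to_numpy(float)
    sidecar = path.with_suffix(path.suffix + ".json")
    fs = None
    if sidecar.exists():
        fs = float(json.loads(sidecar.read_text())["fs"])
    dt = np.diff(t)
    if len(dt):
        if fs is None:
            if np.ptp(dt) > 1e-6 * max(abs(dt).max(), 1e-12):
                raise ValueError(f"{path}: non-uniform time column and no fs sidecar")
            fs = 1.0 / dt.mean()
        elif np.abs(dt - 1.0 / fs).max() > 1e-6 * max(1.0 / fs, 1e-12):
            raise ValueError(f"{path}: time column inconsistent with sidecar fs")
    elif fs is None:
        raise ValueError(f"{path}: cannot infer sampling rate")
    chans = [c for c in df.columns if c != "time"]
    data = df[chans].to_numpy(float)
    if data.shape[1] == 1:
        data = data[:, 0]
    return Signal(data, fs=fs, channel_names=tuple(chans) if data.ndim == 2 else (chans[0],))
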