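"""Core data containers shared across the pipeline.

A :class:`Signal` is the common currency: a uniformly sampled waveform with one
to three channels and a known sampling rate.  A :class:`PeakSet` carries
detected (or ground-truth) fiducial sample indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Signal", "PeakSet"]


@dataclass
class Signal:
    """Uniformly sampled waveform.

    Parameters
    ----------
    data : ndarray
        Shape ``(n,)`` for a single channel or ``(n, ch)`` for multichannel
        (channel order red, green, blue for camera PPG).
    fs : float
        Sampling rate in Hz; must be positive.
    channel_names : tuple of str, optional
        Labels for the channels (defaults to ``ch0``, ``ch1`` ...).
    """

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.data.ndim not in (1, 2):
            raise ValueError("signal data must be 1-D or 2-D (samples x channels)")
        if self.channel_names is None:
            self.channel_names = tuple(f"ch{i}" for i in range(self.n_channels))
        elif len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length does not match channel count")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return 1 if self.data.ndim == 1 else self.data.shape[1]

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel(self, key: int | str) -> "Signal":
        """Single-channel view by index or name."""
        if isinstance(key, str):
            key = self.channel_names.index(key)
        if self.data.ndim == 1:
            if key != 0:
                raise IndexError("single-channel signal")
            return Signal(self.data, self.fs, (self.channel_names[0],))
        return Signal(self.data[:, key], self.fs, (self.channel_names[key],))

    def as_2d(self) -> np.ndarray:
        """Data with an explicit channel axis, shape (n, ch)."""
        return self.data[:, None] if self.data.ndim == 1 else self.data


@dataclass
class PeakSet:
    """Strictly increasing fiducial sample indices.

    ``kind`` distinguishes peaks from valleys; ``fiducial`` optionally tags
    each index with the ECG wave it marks (P, Q, R, S or T).
    """

    indices: np.ndarray
    kind: str = "peak"
    fiducial: tuple[str, ...] | None = None
    amplitudes: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.kind not in ("peak", "valley"):
            raise ValueError("kind must be 'peak' or 'valley'")
        if self.indices.size > 1 and not np.all(np.diff(self.indices) > 0):
            raise ValueError("peak indices must be strictly increasing")
        if self.fiducial is not None and len(self.fiducial) != self.indices.size:
            raise ValueError("fiducial tags must match index count")

    def __len__(self) -> int:
        return int(self.indices.size)

    def __iter__(self):
        return iter(self.indices)

    def to_frame(self):
        """Serialize as a pandas DataFrame (index, kind, fiducial)."""
        import pandas as pd

        fid = self.fiducial if self.fiducial is not None else [""] * len(self)
        return pd.DataFrame(
            {"index": self.indices, "kind": self.kind, "fiducial": list(fid)}
        )
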