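"""Peak, valley and PQRST fiducial detection.

R-peaks (ECG) and pulse peaks (PPG) are found with the two event-related
moving averages (TERMA) scheme: a short moving average tuned to the event
(QRS complex / systolic wave) is compared against a long moving average tuned
to one full beat; contiguous runs where the event average exceeds the
offset-raised cycle average are blocks of interest, and the signal argmax of
each sufficiently long block is the peak.  Detection operates on the squared
positive part of the mean-removed signal, which makes it invariant to
positive affine rescaling of the input.

Note on naming: the systolic PPG maximum is called the pulse peak here
(sometimes referred to as the diastolic peak in the smartphone-PPG
literature).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PeakSet, Signal

__all__ = [
    "TermaProfile",
    "ECG_PROFILE",
    "PPG_PROFILE",
    "terma_detect",
    "detect_valleys",
    "locate_pqrst",
]


@dataclass(frozen=True)
class TermaProfile:
    """Window spans in milliseconds plus the block-acceptance offset.

    offset_beta raises the cycle average by a fraction before comparison; it
    is the knob to adjust manually on recordings with unusual morphology.
    """

    event_window: float = 97.0
    cycle_window: float = 611.0
    offset_beta: float = 0.08
    min_separation: float = 200.0

    def __post_init__(self) -> None:
        if min(self.event_window, self.cycle_window, self.min_separation) <= 0:
            raise ValueError("all TERMA windows must be positive")
        if self.event_window >= self.cycle_window:
            raise ValueError("event_window must be shorter than cycle_window")


# QRS is ~100 ms wide; a systolic PPG wave is slightly broader and smoother.
ECG_PROFILE = TermaProfile(event_window=97.0, cycle_window=611.0, offset_beta=0.08)
PPG_PROFILE = TermaProfile(event_window=111.0, cycle_window=667.0, offset_beta=0.02)


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average with edge-shortened windows."""
    kernel = np.ones(w)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def terma_detect(x: Signal, profile: TermaProfile | None = None) -> PeakSet:
    """Two-moving-average peak detection on a single-channel signal."""
    if x.data.ndim != 1:
        raise ValueError("terma_detect expects a single channel")
    profile = profile or ECG_PROFILE
    fs = x.fs
    w_event = max(1, int(round(profile.event_window * fs / 1000.0)))
    w_cycle = max(w_event + 1, int(round(profile.cycle_window * fs / 1000.0)))
    if w_cycle > x.n_samples:
        raise ValueError("cycle window longer than the signal")

    centred = x.data - x.data.mean()
    energy = np.clip(centred, 0.0, None) ** 2
    ma_event = _moving_average(energy, w_event)
    ma_cycle = _moving_average(energy, w_cycle)
    # block threshold: offset-raised cycle average plus a global level term,
    # which suppresses low-amplitude bumps (T/P waves) between distant beats
    interest = ma_event > ma_cycle * (1.0 + profile.offset_beta) + profile.offset_beta * energy.mean()

    # contiguous blocks of interest
    edges = np.diff(interest.astype(int))
    starts = np.nonzero(edges == 1)[0] + 1
    stops = np.nonzero(edges == -1)[0] + 1
    if interest.size and interest[0]:
        starts = np.insert(starts, 0, 0)
    if interest.size and interest[-1]:
        stops = np.append(stops, interest.size)

    peaks: list[int] = []
    for a, b in zip(starts, stops):
        if b - a < w_event:  # too short to be the event
            continue
        peaks.append(a + int(np.argmax(x.data[a:b])))  # argmax -> earliest on ties

    # enforce minimum separation, keeping the larger amplitude
    min_sep = int(round(profile.min_separation * fs / 1000.0))
    kept: list[int] = []
    for p in peaks:
        if kept and p - kept[-1] < min_sep:
            if x.data[p] > x.data[kept[-1]]:
                kept[-1] = p
        else:
            kept.append(p)
    return PeakSet(np.array(kept, dtype=int), "peak")


def detect_valleys(x: Signal, peaks: PeakSet) -> PeakSet:
    """One valley (argmin) between each consecutive peak pair."""
    if x.data.ndim != 1:
        raise ValueError("detect_valleys expects a single channel")
    if len(peaks) < 2:
        raise ValueError("need at least 2 peaks to locate valleys")
    idx = []
    for a, b in zip(peaks.indices[:-1], peaks.indices[1:]):
        idx.append(a + 1 + int(np.argmin(x.data[a + 1 : b])))
    return PeakSet(np.array(idx, dtype=int), "valley")


# search windows around R in ms: (lo, hi, mode)
_PQRST_WINDOWS = {
    "P": (-250.0, -80.0, "max"),
    "Q": (-80.0, 0.0, "min"),
    "S": (0.0, 80.0, "min"),
    "T": (80.0, 400.0, "max"),
}


def locate_pqrst(cycle: np.ndarray, r_index: int, fs: float) -> PeakSet:
    """Locate the five ECG fiducials within one cycle given the R position.

    Q and S are the minima within 80 ms before/after R; P is the maximum in
    (-250, -80) ms and T the maximum in (+80, +400) ms.  A fiducial whose
    search window falls outside the cycle is marked absent (omitted from the
    returned set).
    """
    cycle = np.asarray(cycle, float)
    n = len(cycle)
    if not 0 <= r_index < n:
        raise ValueError("r_index outside the cycle")
    found: list[tuple[int, str, float]] = [(int(r_index), "R", float(cycle[r_index]))]
    for name, (lo_ms, hi_ms, mode) in _PQRST_WINDOWS.items():
        lo = r_index + int(round(lo_ms * fs / 1000.0))
        hi = r_index + int(round(hi_ms * fs / 1000.0))
        lo_c, hi_c = max(lo, 0), min(hi, n)
        if hi_c - lo_c < 2 or (name in ("P", "T") and (hi > n or lo < 0)):
            continue  # window exceeds cycle bounds -> absent
        seg = cycle[lo_c:hi_c]
        j = int(np.argmax(seg)) if mode == "max" else int(np.argmin(seg))
        found.append((lo_c + j, name, float(seg[j])))
    found.sort(key=lambda t: t[0])
    # guard against degenerate cycles where two windows collapse to one index
    dedup: list[tuple[int, str, float]] = []
    for f in found:
        if not dedup or f[0] > dedup[-1][0]:
            dedup.append(f)
    found = dedup
    return PeakSet(
        np.array([f[0] for f in found]),
        "peak",
        fiducial=tuple(f[1] for f in found),
        amplitudes=np.array([f[2] for f in found]),
    )
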