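"""Cycle-wise PPG-to-ECG translation via truncated DCT regression.

The method maps one cardiac cycle of detrended PPG to one cardiac cycle of
detrended single-lead ECG.  Both signals are cut into per-beat cycles at the
PPG pulse peaks (the ECG cut points lag by the estimated pulse-transit
offset), each cycle is linearly resampled to a fixed length L, transformed
with an orthonormal type-II DCT and truncated to its first L_P (PPG) / L_E
(ECG) coefficients.  A regression model — closed-form ridge, or a small
feed-forward network (two hidden layers, batch-normalized, L1-penalized,
trained with mean-absolute-error loss and Adam under a staircase exponential
learning-rate decay) — predicts the ECG coefficients from the PPG
coefficients; the inverse DCT reconstructs the waveform.  At test time only
PPG pulse peaks are needed: no ECG, no synchronization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import dct as _dct, idct as _idct

from .core import PeakSet, Signal
from .metrics import dirichlet_distance, mae_sae, pearson
from .nn import Activation, BatchNorm, Dense, Sequential, fit_regressor, predict, staircase_exponential

__all__ = [
    "CyclePair",
    "P2eSpec",
    "pair_cycles",
    "split_cycles",
    "dct_truncate",
    "idct_reconstruct",
    "fit_p2e",
    "PulseToEcgModel",
    "PulseToEcgResults",
    "reconstruct_ecg",
    "coefficient_sweep",
]


@dataclass
class CyclePair:
    """One cardiac cycle of PPG and (optionally) ECG, resampled to length L."""

    ppg: np.ndarray
    ecg: np.ndarray | None
    start: int  # pulse-peak sample index opening the cycle (PPG timeline)
    end: int  # next pulse-peak index
    native_len: int = 0
    subject: object | None = None

    def __post_init__(self) -> None:
        self.ppg = np.asarray(self.ppg, float)
        if self.ecg is not None:
            self.ecg = np.asarray(self.ecg, float)
            if self.ecg.shape != self.ppg.shape:
                raise ValueError("PPG and ECG cycles must share the resampled length")
        if not self.native_len:
            self.native_len = self.end - self.start


@dataclass(frozen=True)
class P2eSpec:
    """Configuration of the coefficient-regression stage."""

    config: str = "ffnn"  # 'ridge' | 'ffnn'
    L: int = 300  # fixed cycle length before the DCT
    L_P: int = 150  # PPG coefficients kept
    L_E: int = 150  # ECG coefficients kept
    ridge_lambda: float = 1e-3
    hidden: tuple[int, ...] = (175, 175)
    activation: str = "selu"  # 'tanh' selectable
    l1: float = 1e-5
    batch_size: int = 100
    max_epochs: int = 1000
    lr: float = 1e-3
    lr_decay: float = float(np.exp(-0.1))
    lr_decay_every: int = 100
    patience: int = 25
    val_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.config not in ("ridge", "ffnn"):
            raise ValueError("config must be 'ridge' or 'ffnn'")
        if not (1 <= self.L_P <= self.L and 1 <= self.L_E <= self.L):
            raise ValueError("coefficient counts must lie in [1, L]")
        if any(h <= 0 for h in self.hidden):
            raise ValueError("hidden widths must be positive")
        if self.ridge_lambda < 0:
            raise ValueError("ridge penalty must be non-negative")


# ---------------------------------------------------------------------------
# cycle pairing and DCT


def _resample(x: np.ndarray, L: int) -> np.ndarray:
    if len(x) < 3:
        raise ValueError("cycle too short to resample")
    return np.interp(np.linspace(0.0, len(x) - 1.0, L), np.arange(len(x)), x)


def _match_peaks(r: np.ndarray, p: np.ndarray, max_lag: int) -> list[tuple[int, int]]:
    """Match each R-peak to the first pulse peak within (0, max_lag] after it."""
    matches = []
    j = 0
    for ri in r:
        while j < len(p) and p[j] <= ri:
            j += 1
        if j < len(p) and p[j] - ri <= max_lag:
            matches.append((int(ri), int(p[j])))
    return matches


def estimate_lag(r_peaks: PeakSet, ppg_peaks: PeakSet, fs: float, max_lag_s: float = 0.5) -> int:
    """Median offset (samples) between matched R-peaks and pulse peaks."""
    matches = _match_peaks(r_peaks.indices, ppg_peaks.indices, int(max_lag_s * fs))
    if not matches:
        raise ValueError("no R-peak / pulse-peak matches within the lag window")
    return int(round(float(np.median([p - r for r, p in matches]))))


def pair_cycles(
    ppg: Signal,
    ecg: Signal,
    ppg_peaks: PeakSet,
    r_peaks: PeakSet,
    L: int = 300,
    unmatched_tol: float = 0.2,
    subject: object | None = None,
    guard_s: float = 0.04,
) -> list[CyclePair]:
    """Synchronize the two signals and cut them into resampled cycle pairs.

    The global lag is the median offset between matched (R-peak, pulse-peak)
    pairs; cycles are cut at successive pulse peaks on the PPG timeline and
    at the lag-shifted positions on the ECG timeline.  Beats where either
    cycle would be truncated are dropped.

    Cut points are backed off by ``guard_s`` seconds from the reference peak
    so that one-sample peak-detection jitter cannot flip the R spike between
    the two ends of the resampled cycle (which would make the regression
    target bimodal across recordings).
    """
    if ppg.fs != ecg.fs:
        raise ValueError("PPG and ECG must share the sampling rate")
    if len(ppg_peaks) < 2 or len(r_peaks) < 2:
        raise ValueError("need at least 2 peaks on each signal")
    fs = ppg.fs
    matches = _match_peaks(r_peaks.indices, ppg_peaks.indices, int(0.5 * fs))
    n_expect = max(len(r_peaks), len(ppg_peaks)) - 1  # last beat may be cut
    if len(matches) < (1 - unmatched_tol) * n_expect:
        unmatched = n_expect - len(matches)
        raise ValueError(
            f"{unmatched} of {n_expect} beats could not be matched between the "
            "ECG R-peaks and PPG pulse peaks; check peak detection"
        )
    lag = int(round(float(np.median([p - r for r, p in matches]))))
    guard = int(round(guard_s * fs))

    x_p = ppg.data if ppg.data.ndim == 1 else ppg.data[:, 0]
    x_e = ecg.data if ecg.data.ndim == 1 else ecg.data[:, 0]
    pairs: list[CyclePair] = []
    pk = ppg_peaks.indices - guard
    for a, b in zip(pk[:-1], pk[1:]):
        ea, eb = a - lag, b - lag
        if ea < 0 or eb > len(x_e):
            continue  # truncated beat
        if b > len(x_p):
            continue
        try:
            cp = _resample(x_p[a:b], L)
            ce = _resample(x_e[ea:eb], L)
        except ValueError:
            continue
        pairs.append(CyclePair(cp, ce, int(a), int(b), subject=subject))
    return pairs


def split_cycles(
    ppg: Signal, ppg_peaks: PeakSet, L: int = 300, guard_s: float = 0.04
) -> list[CyclePair]:
    """Cut a PPG alone into resampled cycles (test-time path: no ECG needed).

    Uses the same guard back-off from the pulse peaks as :func:`pair_cycles`
    so test-time cycles match the phase convention the model was trained on.
    """
    if len(ppg_peaks) < 2:
        raise ValueError("no detectable cycles: need at least 2 pulse peaks")
    x_p = ppg.data if ppg.data.ndim == 1 else ppg.data[:, 0]
    guard = int(round(guard_s * ppg.fs))
    out = []
    pk = ppg_peaks.indices - guard
    for a, b in zip(pk[:-1], pk[1:]):
        if b > len(x_p) or a < 0:
            continue
        out.append(CyclePair(_resample(x_p[a:b], L), None, int(a), int(b)))
    return out


def dct_truncate(cycle: np.ndarray, L_keep: int) -> np.ndarray:
    """First ``L_keep`` orthonormal type-II DCT coefficients of a cycle."""
    cycle = np.asarray(cycle, float)
    if not 1 <= L_keep <= len(cycle):
        raise ValueError(f"L_keep={L_keep} outside [1, {len(cycle)}]")
    return _dct(cycle, type=2, norm="ortho")[:L_keep]


def idct_reconstruct(coeffs: np.ndarray, L: int) -> np.ndarray:
    """Zero-pad coefficients to length L and inverse-transform."""
    coeffs = np.asarray(coeffs, float)
    if len(coeffs) > L:
        raise ValueError("more coefficients than output samples")
    full = np.zeros(L)
    full[: len(coeffs)] = coeffs
    return _idct(full, type=2, norm="ortho")


# ---------------------------------------------------------------------------
# the model


class _RidgeMap:
    """Closed-form multi-output ridge: W = (X'X + lam I)^-1 X'Y, centered."""

    def __init__(self, lam: float):
        self.lam = lam
        self.W: np.ndarray | None = None
        self.x_mean: np.ndarray | None = None
        self.y_mean: np.ndarray | None = None

    def fit(self, X: np.ndarray, Y: np.ndarray) -> None:
        self.x_mean = X.mean(axis=0)
        self.y_mean = Y.mean(axis=0)
        Xc, Yc = X - self.x_mean, Y - self.y_mean
        gram = Xc.T @ Xc + self.lam * np.eye(X.shape[1])
        if self.lam == 0:
            cond = np.linalg.cond(gram)
            if not np.isfinite(cond) or cond > 1e12:
                raise np.linalg.LinAlgError(
                    "singular design matrix with no penalty; set ridge_lambda > 0"
                )
        self.W = np.linalg.solve(gram, Xc.T @ Yc)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_mean) @ self.W + self.y_mean


def _build_ffnn(spec: P2eSpec, rng: np.random.Generator) -> tuple[Sequential, list]:
    layers = []
    hidden_weights = []
    d = spec.L_P
    for width in spec.hidden:
        dense = Dense(d, width, rng)
        hidden_weights.append(dense.weight)
        layers += [dense, Activation(spec.activation), BatchNorm(width)]
        d = width
    layers.append(Dense(d, spec.L_E, rng))
    return Sequential(*layers), hidden_weights


@dataclass
class PulseToEcgResults:
    """Fitted PPG-to-ECG mapping plus training diagnostics."""

    spec: P2eSpec
    mapper: object  # _RidgeMap or Sequential
    history: object | None = None
    n_train: int = 0
    lag: int | None = None
    fs: float | None = None

    def predict_coeffs(self, c_p: np.ndarray) -> np.ndarray:
        c_p = np.atleast_2d(np.asarray(c_p, float))
        if isinstance(self.mapper, _RidgeMap):
            out = self.mapper.predict(c_p)
        else:
            out = predict(self.mapper, c_p)
        return out

    def predict_cycle(self, ppg_cycle: np.ndarray) -> np.ndarray:
        """Full-cycle path: resampled PPG cycle in, ECG cycle (length L) out."""
        c_p = dct_truncate(np.asarray(ppg_cycle, float), self.spec.L_P)
        c_e = self.predict_coeffs(c_p)[0]
        return idct_reconstruct(c_e, self.spec.L)

    def evaluate(self, pairs: list[CyclePair]) -> pd.DataFrame:
        """Per-cycle reconstruction metrics against the reference ECG."""
        rows = []
        for i, pair in enumerate(pairs):
            if pair.ecg is None:
                raise ValueError("evaluation needs reference ECG cycles")
            rec = self.predict_cycle(pair.ppg)
            mae, _ = mae_sae(pair.ecg, rec)
            rows.append(
                {
                    "cycle": i,
                    "subject": pair.subject,
                    "p_corr": pearson(pair.ecg, rec),
                    "mae": mae,
                    "l_dir": dirichlet_distance(pair.ecg, rec),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "PPG-to-ECG translation (cycle-wise DCT regression)",
            "=" * 52,
            f"configuration : {self.spec.config}",
            f"cycle length L: {self.spec.L}   L_P={self.spec.L_P}  L_E={self.spec.L_E}",
            f"training pairs: {self.n_train}",
        ]
        if self.spec.config == "ridge":
            lines.append(f"ridge lambda  : {self.spec.ridge_lambda:g}")
        else:
            lines.append(
                f"hidden layers : {self.spec.hidden} ({self.spec.activation}), "
                f"L1={self.spec.l1:g}, params={self.mapper.n_parameters()}"
            )
        if self.history is not None:
            lines.append(
                f"best epoch    : {self.history.best_epoch} "
                f"(val MAE {min(self.history.val_loss):.4f}, "
                f"early stop: {self.history.stopped_early})"
            )
        return "\n".join(lines)


class PulseToEcgModel:
    """Model object: cycle pairs in, fitted coefficient regression out."""

    def __init__(self, pairs: list[CyclePair], spec: P2eSpec | None = None):
        if len(pairs) < 10:
            raise ValueError("need at least 10 cycle pairs to fit")
        self.pairs = pairs
        self.spec = spec or P2eSpec()
        L = len(pairs[0].ppg)
        if L != self.spec.L:
            raise ValueError(f"pairs have length {L} but spec.L={self.spec.L}")

    def _design(self) -> tuple[np.ndarray, np.ndarray]:
        X = np.stack([dct_truncate(p.ppg, self.spec.L_P) for p in self.pairs])
        Y = np.stack([dct_truncate(p.ecg, self.spec.L_E) for p in self.pairs])
        return X, Y

    def fit(self, seed: int = 0) -> PulseToEcgResults:
        X, Y = self._design()
        spec = self.spec
        if spec.config == "ridge":
            mapper = _RidgeMap(spec.ridge_lambda)
            mapper.fit(X, Y)
            return PulseToEcgResults(spec, mapper, None, len(X))
        rng = np.random.default_rng(seed)
        net, hidden_weights = _build_ffnn(spec, rng)
        history = fit_regressor(
            net,
            X,
            Y,
            batch_size=spec.batch_size,
            max_epochs=spec.max_epochs,
            lr=spec.lr,
            lr_schedule=staircase_exponential(spec.lr, spec.lr_decay, spec.lr_decay_every),
            patience=spec.patience,
            val_fraction=spec.val_fraction,
            loss="mae",
            l1=spec.l1,
            l1_params=hidden_weights,
            seed=seed,
        )
        return PulseToEcgResults(spec, net, history, len(X))


def fit_p2e(pairs: list[CyclePair], spec: P2eSpec | None = None, seed: int = 0) -> PulseToEcgResults:
    """Functional wrapper: fit the configured mapping on DCT cycle pairs."""
    return PulseToEcgModel(pairs, spec).fit(seed=seed)


def reconstruct_ecg(
    ppg: Signal, ppg_peaks: PeakSet, results: PulseToEcgResults
) -> tuple[Signal, int]:
    """Synthesize a single-lead ECG from a detrended PPG with pulse peaks only.

    Each PPG cycle is resampled, transformed, mapped and inverse-transformed,
    then inverse-resampled to its native beat length so the synthetic ECG
    keeps the subject's rhythm.  Returns the ECG signal covering the span
    between the first and last pulse peak, plus that span's start sample.
    """
    cycles = split_cycles(ppg, ppg_peaks, results.spec.L)
    out = np.zeros(cycles[-1].end - cycles[0].start)
    offset = cycles[0].start
    for cyc in cycles:
        rec = results.predict_cycle(cyc.ppg)
        native = np.interp(
            np.linspace(0.0, results.spec.L - 1.0, cyc.native_len),
            np.arange(results.spec.L),
            rec,
        )
        out[cyc.start - offset : cyc.end - offset] = native
    return Signal(out, ppg.fs, ("ecg_synth",)), offset


def coefficient_sweep(
    pairs: list[CyclePair],
    grid: list[int],
    spec: P2eSpec | None = None,
    test_fraction: float = 0.2,
    seed: int = 0,
    ffnn_epochs: int = 100,
) -> pd.DataFrame:
    """Refit over a grid of PPG DCT coefficient counts; report test metrics."""
    if not grid:
        raise ValueError("empty coefficient grid")
    base = spec or P2eSpec(config="ridge")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pairs))
    n_test = max(1, int(round(test_fraction * len(pairs))))
    test = [pairs[i] for i in perm[:n_test]]
    train = [pairs[i] for i in perm[n_test:]]
    rows = []
    for L_P in grid:
        spec_i = P2eSpec(
            config=base.config,
            L=base.L,
            L_P=int(L_P),
            L_E=base.L_E,
            ridge_lambda=base.ridge_lambda,
            hidden=base.hidden,
            activation=base.activation,
            l1=base.l1,
            batch_size=base.batch_size,
            max_epochs=ffnn_epochs if base.config == "ffnn" else base.max_epochs,
            lr=base.lr,
            patience=base.patience,
        )
        res = fit_p2e(train, spec_i, seed=seed)
        ev = res.evaluate(test)
        rows.append(
            {
                "L_P": int(L_P),
                "mae": float(ev["mae"].mean()),
                "p_corr": float(ev["p_corr"].mean()),
                "l_dir": float(ev["l_dir"].mean()),
            }
        )
    return pd.DataFrame(rows)
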