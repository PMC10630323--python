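"""Vitals regression networks (CNN-Net, MT-Net, ViT-Net) and their training.

Three small architectures estimate heart rate, SpO2 and respiratory rate from
fixed-width PPG segments:

* **CNN-Net** — a short-time Fourier transform front-end feeding a 1-D
  convolutional stack (the STFT frame axis is convolved, frequency bins act
  as channels).
* **MT-Net** — an orthonormal DCT front-end whose output is *added back* to
  the input (a spectral skip connection), then a convolutional stack and a
  relu fully connected head.
* **ViT-Net** — the STFT image cut into tokens, a small transformer encoder,
  mean pooling and a linear head.

All models place batch normalization followed by dropout after the
flattening layer and each dense layer, train with the batch-mean absolute
error loss under an adaptive-moment optimizer, and stop early on validation
loss.  Training configurations: *vital-specific* (one output), *joint* (all
vitals stacked in one output vector, labels z-scaled per vital).
Leave-several-subjects-out (LESSO) evaluation holds entire subjects out of
training and reports the mean and std of per-subject MAEs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json

import numpy as np
import pandas as pd
from scipy.fft import dct as _dct
from scipy.signal import stft as _stft

from .metrics import mae_sae
from .nn import (
    Activation,
    BatchNorm,
    Conv1d,
    Dense,
    Dropout,
    Flatten,
    LayerNorm,
    MaxPool1d,
    Module,
    MultiHeadAttention,
    Sequential,
    fit_regressor,
    plateau_decay,
    predict,
)
from .preprocess import SegmentDataset

__all__ = [
    "FrontendSpec",
    "ModelSpec",
    "TrainSpec",
    "frontend_apply",
    "build_model",
    "VitalsRegressor",
    "VitalsResults",
    "train_vitals",
    "lesso_split",
    "lesso_evaluate",
    "window_size_search",
]


@dataclass(frozen=True)
class FrontendSpec:
    """Spectral front-end: 'stft', 'dct' (optionally with the ADD skip) or 'none'."""

    mode: str = "dct"
    stft_window: int = 128
    stft_hop: int = 64
    dct_orthonormal: bool = True
    add_skip: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("stft", "dct", "none"):
            raise ValueError("mode must be stft, dct or none")
        if self.add_skip and self.mode != "dct":
            raise ValueError("add_skip requires a length-preserving transform (dct)")


def frontend_apply(segments: np.ndarray, spec: FrontendSpec, fs: float | None = None):
    """Apply the spectral front-end to a batch of segments.

    segments: (N, L, ch).  stft mode returns the magnitude array
    (N, frames, bins*ch); dct mode returns (N, L, ch) coefficients (plus the
    input when add_skip); none returns the input.  With ``fs`` given in stft
    mode, the bin frequencies are returned alongside.
    """
    segments = np.asarray(segments, float)
    if segments.ndim == 2:
        segments = segments[:, :, None]
    n, L, ch = segments.shape
    if spec.mode == "none":
        return segments
    if spec.mode == "dct":
        norm = "ortho" if spec.dct_orthonormal else None
        out = _dct(segments, type=2, norm=norm, axis=1)
        if spec.add_skip:
            out = out + segments
        return out
    # stft
    win = min(spec.stft_window, L)
    hop = min(spec.stft_hop, max(1, win // 2))
    if win > L:
        raise ValueError("stft window longer than the segment")
    freqs, _, Z = _stft(
        segments, fs=fs or 1.0, axis=1, nperseg=win, noverlap=win - hop,
        padded=False, boundary=None,
    )
    # Z: (N, bins, ch, frames) -> (N, frames, bins*ch)
    mag = np.abs(Z).transpose(0, 3, 1, 2).reshape(n, Z.shape[-1], -1)
    if fs is not None:
        return mag, freqs
    return mag


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description; defaults sized for kilobyte-scale models."""

    name: str = "mt_net"  # cnn_net | mt_net | vit_net
    frontend: FrontendSpec | None = None
    conv_filters: tuple[int, ...] = (16, 32, 64)
    conv_kernel: int = 5
    pool: int = 2
    dense: tuple[int, ...] = (64,)
    dropout: float = 0.2
    n_outputs: int = 1
    vit_tokens: int = 16
    vit_width: int = 64
    vit_blocks: int = 2
    vit_heads: int = 4

    def resolved_frontend(self) -> FrontendSpec:
        if self.frontend is not None:
            return self.frontend
        if self.name == "mt_net":
            return FrontendSpec(mode="dct", add_skip=True)
        return FrontendSpec(mode="stft")

    def __post_init__(self) -> None:
        if self.name not in ("cnn_net", "mt_net", "vit_net"):
            raise ValueError(f"unknown model {self.name!r}")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout rate must lie in [0, 1)")


class _TransformerBlock(Module):
    def __init__(self, dim: int, heads: int, rng):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, heads, rng)
        self.norm2 = LayerNorm(dim)
        self.ff1 = Dense(dim, 2 * dim, rng)
        self.ff2 = Dense(2 * dim, dim, rng)

    def forward(self, x):
        x = x + self.attn(self.norm1(x))
        return x + self.ff2(self.ff1(self.norm2(x)).gelu())


class VitalsNet(Module):
    """One of the three architectures; the front-end runs as fixed numpy
    preprocessing (no trainable parameters, no gradient needed)."""

    def __init__(self, spec: ModelSpec, input_len: int, n_channels: int, rng):
        self.spec = spec
        self.frontend = spec.resolved_frontend()
        self.input_len = input_len
        self.n_channels = n_channels

        feat = frontend_apply(np.zeros((1, input_len, n_channels)), self.frontend)
        _, L, C = feat.shape

        if spec.name == "vit_net":
            tokens = min(spec.vit_tokens, L)
            self.patch_len = L // tokens
            self.tokens = tokens
            self.embed = Dense(self.patch_len * C, spec.vit_width, rng)
            self.blocks = [
                _TransformerBlock(spec.vit_width, spec.vit_heads, rng)
                for _ in range(spec.vit_blocks)
            ]
            self.head = Dense(spec.vit_width, spec.n_outputs, rng)
            return

        layers: list[Module] = []
        c_in = C
        for f in spec.conv_filters:
            if L < 2:  # front-end output too short for further convolution
                break
            k = min(spec.conv_kernel, L)
            layers += [Conv1d(c_in, f, k, rng), Activation("relu")]
            L = L - k + 1
            if L // spec.pool >= 2:
                layers.append(MaxPool1d(spec.pool))
                L //= spec.pool
            c_in = f
        layers.append(Flatten())
        d = L * c_in
        layers += [BatchNorm(d), Dropout(spec.dropout)]
        head_act = "relu" if spec.name == "mt_net" else "relu"
        for width in spec.dense:
            layers += [Dense(d, width, rng), Activation(head_act), BatchNorm(width), Dropout(spec.dropout)]
            d = width
        layers.append(Dense(d, spec.n_outputs, rng))
        self.net = Sequential(*layers)

    def forward(self, x):
        from .nn import Tensor

        data = x.data if isinstance(x, Tensor) else np.asarray(x, float)
        if data.ndim == 2:
            data = data[:, :, None]
        feat = Tensor(frontend_apply(data, self.frontend))
        if self.spec.name == "vit_net":
            B, L, C = feat.shape
            t, p = self.tokens, self.patch_len
            tok = feat.data[:, : t * p, :].reshape(B, t, p * C)
            h = self.embed(Tensor(tok))
            for blk in self.blocks:
                h = blk(h)
            return self.head(h.mean(axis=1))
        return self.net(feat)


def build_model(
    spec: ModelSpec, input_len: int, n_channels: int = 1, seed: int = 0
) -> VitalsNet:
    """Construct a trainable network; raises at build time on shape problems."""
    rng = np.random.default_rng(seed)
    model = VitalsNet(spec, input_len, n_channels, rng)
    # shape smoke check with a two-sample batch
    out = predict(model, np.zeros((2, input_len, n_channels)))
    if out.shape != (2, spec.n_outputs):
        raise ValueError(f"model output shape {out.shape} != (2, {spec.n_outputs})")
    model.train()
    return model


@dataclass(frozen=True)
class TrainSpec:
    """Optimization settings shared by the vitals networks."""

    batch_size: int = 128
    max_epochs: int = 1000
    lr: float = 1e-3
    patience: int = 20
    val_fraction: float = 0.15
    test_fraction: float = 0.10
    lesso_subjects: int = 5
    plateau_factor: float = 0.1
    plateau_patience: int = 10
    scale_labels: bool | None = None  # default: only for joint (multi-output)
    seed: int = 0


@dataclass
class VitalsResults:
    """Fitted vitals network with label scaling and training history."""

    model: VitalsNet
    spec: ModelSpec
    train_spec: TrainSpec
    vital_names: tuple[str, ...]
    label_mean: np.ndarray
    label_scale: np.ndarray
    history: object = None
    test_mae: dict | None = None

    def predict(self, segments: np.ndarray) -> np.ndarray:
        """Predicted vitals on the original label scale, shape (N, N_v)."""
        segments = np.asarray(segments, float)
        if segments.ndim == 2:
            segments = segments[:, :, None]
        raw = predict(self.model, segments)
        return raw * self.label_scale + self.label_mean

    def predictions_frame(self, segments: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(self.predict(segments), columns=list(self.vital_names))

    def evaluate(self, ds: SegmentDataset) -> pd.DataFrame:
        pred = self.predict(ds.segments)
        rows = []
        for j, name in enumerate(self.vital_names):
            mae, sae = mae_sae(ds.labels[:, j], pred[:, j])
            rows.append({"vital": name, "mae": mae, "sae": sae})
        return pd.DataFrame(rows).set_index("vital")

    def summary(self) -> str:
        lines = [
            f"Vitals network: {self.spec.name}",
            "=" * 40,
            f"outputs       : {', '.join(self.vital_names)}",
            f"parameters    : {self.model.n_parameters()}",
            f"front-end     : {self.model.frontend.mode}"
            + (" + skip" if self.model.frontend.add_skip else ""),
        ]
        if self.history is not None:
            lines.append(
                f"best epoch    : {self.history.best_epoch} "
                f"(val MAE {min(self.history.val_loss):.4f})"
            )
        if self.test_mae:
            for k, v in self.test_mae.items():
                lines.append(f"test MAE {k:>5}: {v:.3f}")
        return "\n".join(lines)


class VitalsRegressor:
    """Model object binding a segment dataset to an architecture."""

    def __init__(self, ds: SegmentDataset, spec: ModelSpec, train_spec: TrainSpec | None = None):
        if len(ds) == 0:
            raise ValueError("empty dataset")
        if spec.n_outputs != ds.n_vitals:
            raise ValueError(
                f"model outputs ({spec.n_outputs}) must match dataset vitals ({ds.n_vitals})"
            )
        self.ds = ds
        self.spec = spec
        self.train_spec = train_spec or TrainSpec()

    def fit(self, seed: int | None = None) -> VitalsResults:
        tr = self.train_spec
        seed = tr.seed if seed is None else seed
        ds = self.ds
        scale = tr.scale_labels if tr.scale_labels is not None else ds.n_vitals > 1
        if scale:
            mu = ds.labels.mean(axis=0)
            sd = ds.labels.std(axis=0)
            sd[sd == 0] = 1.0
        else:
            mu = np.zeros(ds.n_vitals)
            sd = np.ones(ds.n_vitals)
        y = (ds.labels - mu) / sd

        rng = np.random.default_rng(seed)
        n = len(ds)
        perm = rng.permutation(n)
        n_test = int(round(tr.test_fraction * n))
        test_idx, rest = perm[:n_test], perm[n_test:]
        seg_len = ds.segments.shape[1]

        model = build_model(self.spec, seg_len, ds.n_channels, seed=seed)
        history = fit_regressor(
            model,
            ds.segments[rest],
            y[rest],
            batch_size=tr.batch_size,
            max_epochs=tr.max_epochs,
            lr=tr.lr,
            plateau=plateau_decay(tr.lr, tr.plateau_factor, tr.plateau_patience),
            patience=tr.patience,
            val_fraction=tr.val_fraction / max(1e-9, 1 - tr.test_fraction),
            loss="mae",
            seed=seed,
        )
        results = VitalsResults(
            model, self.spec, tr, ds.vital_names, mu, sd, history
        )
        if n_test:
            ev = results.evaluate(
                SegmentDataset(
                    ds.segments[test_idx], ds.labels[test_idx], ds.w_s, ds.fs, ds.vital_names
                )
            )
            results.test_mae = ev["mae"].to_dict()
        return results


def train_vitals(
    ds: SegmentDataset, spec: ModelSpec, tr: TrainSpec | None = None, seed: int | None = None
) -> VitalsResults:
    """Functional wrapper over :class:`VitalsRegressor`."""
    return VitalsRegressor(ds, spec, tr).fit(seed=seed)


def lesso_split(
    ds: SegmentDataset, k: int = 5, seed: int = 0
) -> tuple[SegmentDataset, list[SegmentDataset]]:
    """Leave-several-subjects-out: k whole subjects held out, rest for training."""
    if ds.subjects is None:
        raise ValueError("dataset carries no subject provenance")
    subjects = np.array(sorted(set(ds.subjects.tolist())))
    if len(subjects) < k + 1:
        raise ValueError(f"need at least {k + 1} subjects for a {k}-subject holdout")
    rng = np.random.default_rng(seed)
    held = rng.choice(subjects, size=k, replace=False)
    mask = np.isin(ds.subjects, held)
    train = SegmentDataset(
        ds.segments[~mask], ds.labels[~mask], ds.w_s, ds.fs, ds.vital_names, ds.subjects[~mask]
    )
    out = []
    for s in held:
        m = ds.subjects == s
        out.append(
            SegmentDataset(ds.segments[m], ds.labels[m], ds.w_s, ds.fs, ds.vital_names, ds.subjects[m])
        )
    return train, out


def lesso_evaluate(results: VitalsResults, held_out: list[SegmentDataset]) -> pd.DataFrame:
    """Per-subject MAEs plus their mean and std across subjects (mu, sigma)."""
    rows = []
    for sub_ds in held_out:
        pred = results.predict(sub_ds.segments)
        for j, name in enumerate(results.vital_names):
            mae, _ = mae_sae(sub_ds.labels[:, j], pred[:, j])
            rows.append({"subject": sub_ds.subjects[0], "vital": name, "mae": mae})
    df = pd.DataFrame(rows)
    agg = df.groupby("vital")["mae"].agg(mu="mean", sigma=lambda s: s.std(ddof=0))
    return df.merge(agg, on="vital")


def window_size_search(
    segmenter,
    grid: list[float],
    spec: ModelSpec,
    tr: TrainSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-segment, retrain and score for each window size in the grid.

    ``segmenter(w_s)`` must return a :class:`SegmentDataset`.  Reports MAE
    and SAE (std of the absolute errors) per vital on each window's test
    split.
    """
    if not grid:
        raise ValueError("empty window grid")
    rows = []
    for w_s in grid:
        ds = segmenter(w_s)
        res = VitalsRegressor(ds, spec, tr).fit(seed=seed)
        pred = res.predict(ds.segments)
        for j, name in enumerate(res.vital_names):
            mae, sae = mae_sae(ds.labels[:, j], pred[:, j])
            rows.append({"w_s": w_s, "vital": name, "mae": mae, "sae": sae})
    return pd.DataFrame(rows)


def save_checkpoint(results: VitalsResults, path) -> None:
    """Single-file archive: weights + JSON architecture/scaling metadata."""
    import dataclasses

    spec_d = dataclasses.asdict(results.spec)
    if spec_d["frontend"] is None:
        spec_d["frontend"] = dataclasses.asdict(results.model.frontend)
    meta = {
        "spec": spec_d,
        "vital_names": list(results.vital_names),
        "label_mean": results.label_mean.tolist(),
        "label_scale": results.label_scale.tolist(),
        "input_len": results.model.input_len,
        "n_channels": results.model.n_channels,
    }
    state = results.model.state_dict()
    np.savez_compressed(path, meta=np.array(json.dumps(meta)), *state)


def load_checkpoint(path) -> VitalsResults:
    z = np.load(path, allow_pickle=True)
    meta = json.loads(str(z["meta"]))
    spec_d = dict(meta["spec"])
    fe = spec_d.pop("frontend")
    spec = ModelSpec(
        frontend=FrontendSpec(**fe) if fe else None,
        **{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in spec_d.items()
        },
    )
    model = build_model(spec, meta["input_len"], meta["n_channels"])
    state = [z[f"arr_{i}"] for i in range(len(z.files) - 1)]
    model.load_state_dict(state)
    model.eval()
    return VitalsResults(
        model,
        spec,
        TrainSpec(),
        tuple(meta["vital_names"]),
        np.array(meta["label_mean"]),
        np.array(meta["label_scale"]),
    )
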