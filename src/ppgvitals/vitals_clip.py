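"""Contrastive PPG-caption retrieval for one-shot vitals estimation.

Each PPG segment is paired with a templated text caption of its true vitals
("HR is 72.0 beats/min, SpO2 is 97.0 %, RR is 16.0 breaths/min.").  Two
encoders — a 1-D convolutional PPG encoder and a token-embedding text
encoder, each topped with a shared-architecture projection head producing
unit-norm 256-dim embeddings — are pretrained with a symmetric contrastive
objective over the in-batch similarity matrix (learnable temperature).

At query time, a PPG embedding is dotted against a bank of caption
embeddings; the numeric vitals parsed from the top-k captions are averaged
per vital.  Captions may carry extra fields (SBP/DBP, mmHg) that a reader
asking only for HR/SpO2/RR simply ignores.

The default text encoder is a trainable digit-level tokenizer + embedding
with learned positional offsets, so the package builds fully offline; a
pretrained language-model encoder can be plugged in through the
``text_encoder`` hook of :class:`VitalsClip`.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nn import (
    Activation,
    Conv1d,
    Dense,
    Dropout,
    Embedding,
    Flatten,
    LayerNorm,
    MaxPool1d,
    Module,
    Sequential,
    Tensor,
    softmax_cross_entropy,
)
from .nn.optim import Adam

__all__ = [
    "Caption",
    "ConvSpec",
    "PpgEncoderSpec",
    "make_caption",
    "parse_caption",
    "VitalsClip",
    "ClipResults",
    "pretrain_clip",
    "query_vitals",
]

# ---------------------------------------------------------------------------
# captions

_UNITS = {"hr": "beats/min", "rr": "breaths/min", "spo2": "%", "sbp": "mmHg", "dbp": "mmHg"}
_NAMES = {"hr": "HR", "rr": "RR", "spo2": "SpO2", "sbp": "SBP", "dbp": "DBP"}
_ORDER = ("hr", "spo2", "rr", "sbp", "dbp")


@dataclass
class Caption:
    text: str
    parsed: dict[str, float] = field(default_factory=dict)

    @property
    def n_tokens(self) -> int:
        return len(tokenize(self.text))


def make_caption(vitals: dict[str, float], template: int = 0) -> Caption:
    """Deterministic caption text from numeric vitals; round-trips exactly
    through :func:`parse_caption`."""
    fields = [(k, vitals[k]) for k in _ORDER if k in vitals and vitals[k] is not None]
    if not fields:
        raise ValueError("at least one vital is required")
    parts = [f"{_NAMES[k]} is {float(v):g} {_UNITS[k]}" for k, v in fields]
    text = ", ".join(parts) + "."
    return Caption(text, {k: float(f"{float(v):g}") for k, v in fields})


_PATTERNS = {
    "hr": re.compile(r"HR is ([-+0-9.eE]+) beats/min", re.I),
    "rr": re.compile(r"RR is ([-+0-9.eE]+) breaths/min", re.I),
    "spo2": re.compile(r"SpO2 is ([-+0-9.eE]+) %", re.I),
    "sbp": re.compile(r"SBP is ([-+0-9.eE]+) mmHg", re.I),
    "dbp": re.compile(r"DBP is ([-+0-9.eE]+) mmHg", re.I),
}


def parse_caption(text: str, vitals: tuple[str, ...] = ("hr", "spo2", "rr")) -> dict[str, float]:
    """Unit-anchored numeric extraction; fields not asked for are ignored."""
    out = {}
    for key in vitals:
        m = _PATTERNS[key].search(text)
        if m:
            out[key] = float(m.group(1))
    return out


def tokenize(text: str) -> list[str]:
    """Lowercased word / single-digit / punctuation tokens (number-aware)."""
    return re.findall(r"[a-z]+|[0-9]|[%./,]", text.lower())


# ---------------------------------------------------------------------------
# encoders


@dataclass(frozen=True)
class ConvSpec:
    """One PPG-encoder convolution: filters N_f, kernel K_s, stride s."""

    n_f: int
    k_s: int
    s: int = 1
    pool: bool = False

    def __post_init__(self) -> None:
        if min(self.n_f, self.k_s, self.s) <= 0:
            raise ValueError("conv parameters must be positive")


# channels follow the encoder's printed output shapes (8, 8, 16, 32)
_DEFAULT_CONVS = (
    ConvSpec(8, 10, pool=True),
    ConvSpec(8, 5, pool=True),
    ConvSpec(16, 3),
    ConvSpec(32, 3),
)


@dataclass(frozen=True)
class PpgEncoderSpec:
    input_len: int = 1250
    convs: tuple[ConvSpec, ...] = _DEFAULT_CONVS
    embed_dim: int = 256
    dropout: float = 0.2

    def flatten_size(self) -> int:
        L, C = self.input_len, 1
        for c in self.convs:
            L = (L - c.k_s) // c.s + 1
            if c.pool:
                L //= 2
            C = c.n_f
        return L * C


class Projection(Module):
    """Dense to the embedding width, then gelu -> dense -> dropout -> add ->
    layer-norm; output is L2-normalized to unit length."""

    def __init__(self, d_in: int, d_out: int, dropout: float, rng):
        self.dense0 = Dense(d_in, d_out, rng)
        self.dense1 = Dense(d_out, d_out, rng)
        self.drop = Dropout(dropout)
        self.norm = LayerNorm(d_out)

    def forward(self, x: Tensor) -> Tensor:
        h = self.dense0(x)
        p = self.drop(self.dense1(h.gelu()))
        z = self.norm(h + p)
        scale = (z * z).sum(axis=-1, keepdims=True) ** 0.5
        return z / (scale + 1e-12)


class PpgEncoder(Module):
    def __init__(self, spec: PpgEncoderSpec, rng):
        self.spec = spec
        layers: list[Module] = []
        c_in = 1
        for c in spec.convs:
            if c.s != 1:
                raise NotImplementedError("stride 1 convolutions only")
            layers += [Conv1d(c_in, c.n_f, c.k_s, rng), Activation("relu")]
            if c.pool:
                layers.append(MaxPool1d(2))
            c_in = c.n_f
        layers.append(Flatten())
        self.conv = Sequential(*layers)
        self.project = Projection(spec.flatten_size(), spec.embed_dim, spec.dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim == 2:
            x = x.reshape(*x.shape, 1)
        return self.project(self.conv(x))


class TextEncoder(Module):
    """Trainable caption reader: token + positional embeddings, a short
    convolutional stack over the token axis (so multi-digit numbers are
    composed from their digits in place), flatten, then projection."""

    def __init__(self, vocab: dict[str, int], rng, token_dim: int = 32,
                 max_len: int = 48, embed_dim: int = 256, dropout: float = 0.2):
        self.vocab = vocab
        self.max_len = max_len
        self.tok = Embedding(len(vocab) + 1, token_dim, rng)  # +1 for unknown
        self.pos = Embedding(max_len, token_dim, rng)
        self.conv = Sequential(
            Conv1d(token_dim, 32, 3, rng),
            Activation("relu"),
            Conv1d(32, 32, 3, rng),
            Activation("relu"),
            Flatten(),
        )
        flat = (max_len - 4) * 32
        self.project = Projection(flat, embed_dim, dropout, rng)

    def encode_ids(self, texts: list[str]) -> np.ndarray:
        ids = np.zeros((len(texts), self.max_len), dtype=int)
        for i, t in enumerate(texts):
            toks = tokenize(t)[: self.max_len]
            ids[i, : len(toks)] = [self.vocab.get(tk, len(self.vocab)) for tk in toks]
        return ids

    def forward(self, texts: list[str]) -> Tensor:
        ids = self.encode_ids(texts)
        n, T = ids.shape
        emb = self.tok(ids) + self.pos(np.broadcast_to(np.arange(T), (n, T)))
        return self.project(self.conv(emb))


# ---------------------------------------------------------------------------
# the contrastive model


@dataclass
class ClipResults:
    """Pretrained encoders plus a caption bank for querying."""

    ppg_encoder: PpgEncoder
    text_encoder: Module
    log_temperature: Tensor
    history: pd.DataFrame
    bank_embeddings: np.ndarray | None = None
    bank_captions: list[str] | None = None

    def encode_ppg(self, segments: np.ndarray, batch_size: int = 256) -> np.ndarray:
        segments = np.atleast_2d(np.asarray(segments, float))
        self.ppg_encoder.eval()
        out = [
            self.ppg_encoder(Tensor(segments[i : i + batch_size])).data
            for i in range(0, len(segments), batch_size)
        ]
        return np.concatenate(out)

    def encode_text(self, texts: list[str], batch_size: int = 256) -> np.ndarray:
        self.text_encoder.eval()
        out = [
            self.text_encoder(texts[i : i + batch_size]).data
            for i in range(0, len(texts), batch_size)
        ]
        return np.concatenate(out)

    def build_bank(self, captions: list[str]) -> None:
        self.bank_captions = list(captions)
        self.bank_embeddings = self.encode_text(self.bank_captions)

    def save_bank(self, path) -> None:
        with open(path, "w") as fh:
            for text in self.bank_captions:
                fh.write(json.dumps({"text": text, "parsed": parse_caption(text)}) + "\n")

    def query(
        self,
        segment: np.ndarray,
        k: int = 3,
        vitals: tuple[str, ...] = ("hr", "spo2", "rr"),
    ) -> tuple[dict[str, float], list[str]]:
        """Top-k caption retrieval and per-vital averaging."""
        if self.bank_embeddings is None:
            raise ValueError("no caption bank; call build_bank first")
        q = self.encode_ppg(segment)[0]
        scores = self.bank_embeddings @ q
        top = np.argsort(-scores)[:k]
        captions = [self.bank_captions[i] for i in top]
        pred: dict[str, list[float]] = {}
        for text in captions:
            for key, val in parse_caption(text, vitals).items():
                pred.setdefault(key, []).append(val)
        out = {key: float(np.mean(vals)) for key, vals in pred.items()}
        missing = [v for v in vitals if v not in out]
        if missing:
            import warnings

            warnings.warn(f"no caption provided a value for: {missing}", stacklevel=2)
        return out, captions

    def summary(self) -> str:
        n_par = self.ppg_encoder.n_parameters() + self.text_encoder.n_parameters()
        lines = [
            "Contrastive PPG-caption model",
            "=" * 40,
            f"embedding dim : {self.ppg_encoder.spec.embed_dim}",
            f"parameters    : {n_par}",
            f"temperature   : {float(np.exp(self.log_temperature.data)):.3f}",
            f"final loss    : {self.history['loss'].iloc[-1]:.4f}"
            if len(self.history)
            else "",
        ]
        return "\n".join(s for s in lines if s)


class VitalsClip:
    """Model object: (segment, caption) corpus in, pretrained encoders out."""

    def __init__(
        self,
        corpus: list[dict],
        ppg_spec: PpgEncoderSpec | None = None,
        text_encoder: Module | None = None,
    ):
        if len(corpus) < 2:
            raise ValueError("contrastive pretraining needs at least 2 pairs")
        self.corpus = corpus
        seg_len = len(corpus[0]["segment"])
        self.ppg_spec = ppg_spec or PpgEncoderSpec(input_len=seg_len)
        if self.ppg_spec.input_len != seg_len:
            raise ValueError(
                f"corpus segments have length {seg_len}, spec expects {self.ppg_spec.input_len}"
            )
        self._text_encoder = text_encoder

    @staticmethod
    def _batch_loss(e_p: Tensor, e_t: Tensor, log_t: Tensor) -> Tensor:
        logits = (e_p @ e_t.transpose()) * log_t.exp()
        targets = np.arange(logits.shape[0])
        return (
            softmax_cross_entropy(logits, targets)
            + softmax_cross_entropy(logits.transpose(), targets)
        ) * 0.5

    def fit(
        self,
        epochs: int = 60,
        batch_size: int = 256,
        lr: float = 1e-3,
        seed: int = 0,
        val_fraction: float = 0.1,
        patience: int = 8,
        noise_aug: float = 0.1,
    ) -> ClipResults:
        """Symmetric contrastive pretraining with early stopping on the
        validation contrastive loss; the best-validation encoder weights are
        restored at the end."""
        rng = np.random.default_rng(seed)
        segments = np.stack([np.asarray(r["segment"], float) for r in self.corpus])
        captions = [r["caption"] for r in self.corpus]

        vocab: dict[str, int] = {}
        for text in captions:
            for tk in tokenize(text):
                vocab.setdefault(tk, len(vocab) + 1)  # 0 is padding

        ppg_enc = PpgEncoder(self.ppg_spec, rng)
        txt_enc = self._text_encoder or TextEncoder(
            vocab, rng, embed_dim=self.ppg_spec.embed_dim, dropout=self.ppg_spec.dropout
        )
        log_t = Tensor(np.array(np.log(1 / 0.07)), requires_grad=True)
        params = ppg_enc.parameters() + txt_enc.parameters() + [log_t]
        opt = Adam(params, lr=lr)
        ppg_enc.seed_dropout(np.random.default_rng(seed + 1))
        txt_enc.seed_dropout(np.random.default_rng(seed + 2))

        n = len(segments)
        perm = rng.permutation(n)
        n_val = min(max(int(round(val_fraction * n)), 2), n - 2) if val_fraction > 0 else 0
        val_idx, train_idx = perm[:n_val], perm[n_val:]

        labels = [r.get("labels") for r in self.corpus]
        has_labels = all(
            isinstance(lb, dict) and "hr" in lb for lb in labels
        ) and n_val > 0

        def val_loss() -> float:
            """Validation criterion: retrieval HR error of held-out segments
            against the training captions when labels are available (the
            quantity querying mode cares about); otherwise the held-out
            contrastive loss."""
            ppg_enc.eval()
            txt_enc.eval()
            if has_labels:
                e_p = ppg_enc(Tensor(segments[val_idx])).data
                bank = txt_enc([captions[i] for i in train_idx]).data
                top = np.argsort(-(e_p @ bank.T), axis=1)[:, :3]
                errs = []
                for row, vi in zip(top, val_idx):
                    vals = [
                        parse_caption(captions[train_idx[j]], ("hr",)).get("hr")
                        for j in row
                    ]
                    vals = [v for v in vals if v is not None]
                    if vals:
                        errs.append(abs(float(np.mean(vals)) - labels[vi]["hr"]))
                out = float(np.mean(errs)) if errs else np.inf
            else:
                e_p = ppg_enc(Tensor(segments[val_idx]))
                e_t = txt_enc([captions[i] for i in val_idx])
                out = float(self._batch_loss(e_p, e_t, log_t).data)
            ppg_enc.train()
            txt_enc.train()
            return out

        history = []
        best = np.inf
        best_state = None
        bad = 0
        for epoch in range(epochs):
            order = rng.permutation(len(train_idx))
            losses = []
            for start in range(0, len(train_idx) - 1, batch_size):
                idx = train_idx[order[start : start + batch_size]]
                if len(idx) < 2:
                    continue
                opt.zero_grad()
                batch = segments[idx]
                if noise_aug > 0:
                    # fresh noise each pass stops the encoder memorizing the
                    # noise pattern of individual segments
                    batch = batch + rng.normal(0.0, noise_aug, size=batch.shape)
                e_p = ppg_enc(Tensor(batch))
                e_t = txt_enc([captions[i] for i in idx])
                loss = self._batch_loss(e_p, e_t, log_t)
                loss.backward()
                opt.step()
                # clamp the temperature as in standard contrastive training
                log_t.data = np.clip(log_t.data, None, np.log(100.0))
                losses.append(float(loss.data))
            vl = val_loss() if n_val else float(np.mean(losses))
            history.append({"epoch": epoch, "loss": float(np.mean(losses)), "val_loss": vl})
            if vl < best - 1e-9:
                best = vl
                best_state = (
                    ppg_enc.state_dict(),
                    txt_enc.state_dict(),
                    log_t.data.copy(),
                )
                bad = 0
            else:
                bad += 1
                if patience and bad >= patience:
                    break
        if best_state is not None:
            ppg_enc.load_state_dict(best_state[0])
            txt_enc.load_state_dict(best_state[1])
            log_t.data = best_state[2]
        ppg_enc.eval()
        txt_enc.eval()
        results = ClipResults(ppg_enc, txt_enc, log_t, pd.DataFrame(history))
        results.build_bank(captions)
        return results


def pretrain_clip(
    corpus: list[dict], epochs: int = 30, seed: int = 0, batch_size: int = 128
) -> ClipResults:
    """Functional wrapper over :class:`VitalsClip`."""
    return VitalsClip(corpus).fit(epochs=epochs, batch_size=batch_size, seed=seed)


def query_vitals(
    results: ClipResults,
    segment: np.ndarray,
    k: int = 3,
    vitals: tuple[str, ...] = ("hr", "spo2", "rr"),
) -> tuple[dict[str, float], list[str]]:
    """Functional wrapper over :meth:`ClipResults.query`."""
    return results.query(segment, k=k, vitals=vitals)
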