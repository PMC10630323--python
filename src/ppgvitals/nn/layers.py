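"""Network building blocks on top of the autograd engine.

Shapes follow the signal convention used throughout the package: batches of
1-D waveforms are ``(batch, length, channels)``; dense features are
``(batch, features)``.  Initialization is Glorot/Xavier uniform from a
caller-supplied NumPy generator, so builds are reproducible.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = [
    "Module",
    "Dense",
    "Conv1d",
    "MaxPool1d",
    "BatchNorm",
    "LayerNorm",
    "Dropout",
    "Embedding",
    "Activation",
    "Flatten",
    "Sequential",
    "MultiHeadAttention",
]


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Module:
    """Base class: parameter collection, train/eval mode, dropout seeding."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for value in self.__dict__.values():
            if isinstance(value, Module):
                mods.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def seed_dropout(self, rng: np.random.Generator) -> None:
        for m in self.modules():
            if isinstance(m, Dropout):
                m.rng = rng

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> list[np.ndarray]:
        """Parameters plus normalization running statistics."""
        state = [p.data.copy() for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm):
                state += [m.running_mean.copy(), m.running_var.copy()]
        return state

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, s in zip(params, state[: len(params)], strict=True):
            p.data = s.copy()
        i = len(params)
        for m in self.modules():
            if isinstance(m, BatchNorm):
                m.running_mean = state[i].copy()
                m.running_var = state[i + 1].copy()
                i += 2
        if i != len(state):
            raise ValueError("state does not match the module structure")

    def __call__(self, x):
        return self.forward(x)


class Dense(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.weight = Tensor(xavier_uniform(rng, d_in, d_out, (d_in, d_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        return out + self.bias if self.bias is not None else out


class Conv1d(Module):
    """Valid 1-D convolution, stride 1; input (B, L, C_in) -> (B, L-K+1, C_out)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        fan_in, fan_out = kernel * c_in, kernel * c_out
        self.weight = Tensor(
            xavier_uniform(rng, fan_in, fan_out, (kernel * c_in, c_out)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        K, c_in, c_out = self.kernel, self.c_in, self.c_out
        B, L, _ = x.shape
        L_out = L - K + 1
        if L_out < 1:
            raise ValueError(f"input length {L} shorter than kernel {K}")
        win = np.lib.stride_tricks.sliding_window_view(x.data, K, axis=1)  # (B,Lout,Cin,K)
        col = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B, L_out, K * c_in)
        w, b = self.weight, self.bias
        out = Tensor(col @ w.data + b.data, parents=(x, w, b))

        def backward(g):
            if w.requires_grad:
                w._accum(np.einsum("blk,blo->ko", col, g))
            if b.requires_grad:
                b._accum(g.sum(axis=(0, 1)))
            if x.requires_grad or x._parents:
                gcol = (g @ w.data.T).reshape(B, L_out, K, c_in)
                gx = np.zeros_like(x.data)
                for k in range(K):
                    gx[:, k : k + L_out, :] += gcol[:, :, k, :]
                x._accum(gx)

        out._backward = backward
        return out


class MaxPool1d(Module):
    """Non-overlapping max pooling (pool = stride), trimming any odd tail."""

    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x: Tensor) -> Tensor:
        p = self.pool
        B, L, C = x.shape
        L_out = L // p
        trimmed = x.data[:, : L_out * p, :].reshape(B, L_out, p, C)
        arg = trimmed.argmax(axis=2)  # (B, L_out, C)
        out = Tensor(np.take_along_axis(trimmed, arg[:, :, None, :], axis=2)[:, :, 0, :], parents=(x,))

        def backward(g):
            if x.requires_grad or x._parents:
                gx = np.zeros((B, L_out, p, C))
                np.put_along_axis(gx, arg[:, :, None, :], g[:, :, None, :], axis=2)
                full = np.zeros_like(x.data)
                full[:, : L_out * p, :] = gx.reshape(B, L_out * p, C)
                x._accum(full)

        out._backward = backward
        return out


class BatchNorm(Module):
    """Normalize over all axes but the last (feature/channel) axis."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            axes = tuple(range(x.ndim - 1))
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return xhat * self.gamma + self.beta


class LayerNorm(Module):
    """Normalize the last axis per sample."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng: np.random.Generator = np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0:
            return x
        mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * Tensor(mask)


class Embedding(Module):
    def __init__(self, vocab: int, dim: int, rng: np.random.Generator):
        self.weight = Tensor(rng.normal(0.0, 0.02, size=(vocab, dim)), requires_grad=True)

    def forward(self, indices: np.ndarray) -> Tensor:
        indices = np.asarray(indices, dtype=int)
        flat = self.weight.take(indices.ravel())
        return flat.reshape(*indices.shape, self.weight.shape[1])


class Activation(Module):
    def __init__(self, name: str):
        self.name = name

    def forward(self, x: Tensor) -> Tensor:
        return getattr(x, self.name)()


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.shape[0], -1)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def softmax_last(x: Tensor) -> Tensor:
    shift = Tensor(x.data.max(axis=-1, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.heads = heads
        self.dim = dim
        self.q = Dense(dim, dim, rng)
        self.k = Dense(dim, dim, rng)
        self.v = Dense(dim, dim, rng)
        self.out = Dense(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        h, dh = self.heads, D // self.heads

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, T, h, dh).transpose(0, 2, 1, 3)  # (B,h,T,dh)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        attn = softmax_last(scores)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.out(ctx)
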