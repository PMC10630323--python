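"""Adaptive-moment optimizer and learning-rate schedules."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["Adam", "staircase_exponential", "plateau_decay"]


class Adam:
    """Adam with optional L1 penalty applied to a designated parameter subset."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        l1: float = 0.0,
        l1_params: list[Tensor] | None = None,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.l1 = l1
        self._l1_ids = {id(p) for p in (l1_params if l1_params is not None else params)}
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.l1 and id(p) in self._l1_ids:
                g = g + self.l1 * np.sign(p.data)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def staircase_exponential(lr0: float, decay: float = np.exp(-0.1), every: int = 100):
    """Staircase exponential decay: lr = lr0 * decay**floor(epoch / every)."""

    def schedule(epoch: int) -> float:
        return lr0 * decay ** (epoch // every)

    return schedule


def plateau_decay(lr0: float, factor: float = 0.1, patience: int = 10, min_lr: float = 1e-6):
    """Stateful reduce-on-plateau schedule: call ``update(val_loss)`` each epoch."""

    state = {"lr": lr0, "best": np.inf, "bad": 0}

    def update(val_loss: float) -> float:
        if val_loss < state["best"] - 1e-12:
            state["best"] = val_loss
            state["bad"] = 0
        else:
            state["bad"] += 1
            if state["bad"] > patience:
                state["lr"] = max(state["lr"] * factor, min_lr)
                state["bad"] = 0
        return state["lr"]

    return update
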