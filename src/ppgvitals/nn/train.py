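"""Generic mini-batch training loop with early stopping.

Regression fits minimize the batch-mean absolute error (the loss every model
in this package trains with; squared error is available for oracles).  The
loop tracks per-epoch train/validation loss, retains the best-validation
weights, and restores them at the end.  Seeding the generator makes runs
bit-reproducible on a single thread.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .autograd import Tensor
from .layers import Module
from .optim import Adam

__all__ = ["FitHistory", "fit_regressor", "mae_loss"]


def mae_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Batch-mean absolute error: L = (1/|B|) * sum |y - yhat|.

    The sum runs over samples; for vector-valued targets the per-sample
    absolute errors are averaged across output components.
    """
    return (pred - Tensor(target)).abs().mean()


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    return ((pred - Tensor(target)) ** 2).mean()


_LOSSES: dict[str, Callable] = {"mae": mae_loss, "mse": mse_loss}


@dataclass
class FitHistory:
    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"epoch": self.epochs, "train_mae": self.train_loss, "val_mae": self.val_loss}
        )


def fit_regressor(
    model: Module,
    X: np.ndarray,
    y: np.ndarray,
    *,
    batch_size: int = 128,
    max_epochs: int = 1000,
    lr: float = 1e-3,
    lr_schedule: Callable[[int], float] | None = None,
    plateau: Callable[[float], float] | None = None,
    patience: int = 20,
    val_fraction: float = 0.15,
    loss: str = "mae",
    l1: float = 0.0,
    l1_params: list | None = None,
    seed: int = 0,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> FitHistory:
    """Train ``model`` in place; returns the loss history.

    When ``X_val`` is not given, the last ``val_fraction`` of a shuffled copy
    of the data is held out for validation and early stopping.
    """
    if len(X) == 0:
        raise ValueError("empty training set")
    loss_fn = _LOSSES[loss]
    rng = np.random.default_rng(seed)
    model.seed_dropout(np.random.default_rng(seed + 1))

    if X_val is None:
        perm = rng.permutation(len(X))
        n_val = int(round(val_fraction * len(X)))
        n_val = min(max(n_val, 1), len(X) - 1) if val_fraction > 0 else 0
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        X_val, y_val = X[val_idx], y[val_idx]
        X_tr, y_tr = X[train_idx], y[train_idx]
    else:
        X_tr, y_tr = X, y

    opt = Adam(model.parameters(), lr=lr, l1=l1, l1_params=l1_params)
    history = FitHistory()
    best_val = np.inf
    best_state = model.state_dict()
    bad = 0

    for epoch in range(max_epochs):
        if lr_schedule is not None:
            opt.lr = lr_schedule(epoch)
        model.train()
        order = rng.permutation(len(X_tr))
        batch_losses = []
        for start in range(0, len(X_tr), batch_size):
            idx = order[start : start + batch_size]
            opt.zero_grad()
            pred = model(Tensor(X_tr[idx]))
            batch_loss = loss_fn(pred, y_tr[idx])
            if not np.isfinite(batch_loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; lower the learning rate "
                    f"(lr={opt.lr:g}) or check the input scaling"
                )
            batch_loss.backward()
            opt.step()
            batch_losses.append(float(batch_loss.data))

        model.eval()
        if len(X_val):
            val = float(loss_fn(model(Tensor(X_val)), y_val).data)
        else:
            val = float(np.mean(batch_losses))
        history.epochs.append(epoch)
        history.train_loss.append(float(np.mean(batch_losses)))
        history.val_loss.append(val)
        if plateau is not None:
            opt.lr = plateau(val)

        if val < best_val - 1e-9:
            best_val = val
            best_state = model.state_dict()
            history.best_epoch = epoch
            bad = 0
        else:
            bad += 1
            if patience and bad >= patience:
                history.stopped_early = True
                break

    model.load_state_dict(best_state)
    model.eval()
    return history


def predict(model: Module, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
    """Forward pass in eval mode, batched to bound memory."""
    model.eval()
    outs = [model(Tensor(X[i : i + batch_size])).data for i in range(0, len(X), batch_size)]
    return np.concatenate(outs, axis=0)
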