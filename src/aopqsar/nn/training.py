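"""Network training loop: Adam, plateau LR schedule, early stopping.

The schedule mirrors common deep-QSAR practice: a fraction of the
training data is held out for validation; when the validation loss stops
improving for ``plateau_patience`` epochs, the learning rate is divided by
``lr_decay_factor``; a second plateau ends training. The output-layer bias
can be initialized from the class ratio (``log(p/(1-p))``) so the network
starts from the base rate on imbalanced data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .layers import Module


class NetworkData(Protocol):
    """Model-consumable dataset: sized and row-indexable."""

    def __len__(self) -> int: ...

    def take(self, indices: np.ndarray): ...


@dataclass
class NetworkTrainConfig:
    batch_size: int = 32
    max_epochs: int = 60
    validation_fraction: float = 0.10
    plateau_patience: int = 10
    lr_decay_factor: float = 10.0
    early_stop_patience: int = 20
    init_output_bias_from_class_ratio: bool = True
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.validation_fraction < 0.5:
            raise ValueError("0 < validation_fraction < 0.5")
        if self.lr_decay_factor <= 1:
            raise ValueError("lr_decay_factor > 1")


@dataclass
class TrainingHistory:
    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": self.epochs,
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "learning_rate": self.learning_rate,
            }
        )


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _stratified_validation_split(labels, fraction, rng):
    labels = np.asarray(labels)
    val_idx: list[int] = []
    for cls in np.unique(labels):
        cls_idx = np.flatnonzero(labels == cls)
        n_val = max(1, int(round(fraction * len(cls_idx))))
        val_idx.extend(rng.permutation(cls_idx)[:n_val].tolist())
    val = np.sort(np.array(val_idx, dtype=int))
    train = np.setdiff1d(np.arange(len(labels)), val)
    return train, val


def fit_network(
    model: Module,
    data: NetworkData,
    labels: np.ndarray,
    cfg: NetworkTrainConfig,
) -> TrainingHistory:
    """Train ``model`` (must expose ``forward(batch) -> logits`` and an
    ``output_bias`` Tensor) with the plateau schedule described above."""
    labels = np.asarray(labels, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    train_idx, val_idx = _stratified_validation_split(
        labels, cfg.validation_fraction, rng
    )
    if cfg.init_output_bias_from_class_ratio:
        p = labels[train_idx].mean()
        p = min(max(p, 1e-6), 1 - 1e-6)
        model.output_bias.data[:] = np.log(p / (1 - p))

    optimizer = Adam(model.parameters(), lr=cfg.learning_rate)
    history = TrainingHistory()
    best_val = np.inf
    stale = 0
    decayed = False
    since_best = 0

    def eval_loss(indices) -> float:
        model.train(False)
        total, count = 0.0, 0
        for start in range(0, len(indices), 256):
            batch = indices[start: start + 256]
            logits = model.forward(data.take(batch))
            loss = ad.bce_with_logits(logits, labels[batch])
            total += float(loss.data) * len(batch)
            count += len(batch)
        model.train(True)
        return total / max(count, 1)

    for epoch in range(cfg.max_epochs):
        model.train(True)
        order = rng.permutation(train_idx)
        running, seen = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start: start + cfg.batch_size]
            logits = model.forward(data.take(batch))
            loss = ad.bce_with_logits(logits, labels[batch])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {float(loss.data)}"
                )
            model.zero_grad()
            loss.backward()
            optimizer.step()
            running += float(loss.data) * len(batch)
            seen += len(batch)
        val_loss = eval_loss(val_idx)
        history.epochs.append(epoch)
        history.train_loss.append(running / max(seen, 1))
        history.val_loss.append(val_loss)
        history.learning_rate.append(optimizer.lr)

        if val_loss < best_val - 1e-6:
            best_val = val_loss
            stale = 0
            since_best = 0
        else:
            stale += 1
            since_best += 1
        if stale > cfg.plateau_patience:
            if not decayed:
                optimizer.lr /= cfg.lr_decay_factor
                decayed = True
                stale = 0
            else:
                break  # second plateau: stop to avoid overfitting
        if since_best > cfg.early_stop_patience:
            break
    model.train(False)
    return history


def predict_proba(model: Module, data: NetworkData, batch_size: int = 256) -> np.ndarray:
    model.train(False)
    out = []
    n = len(data)
    for start in range(0, n, batch_size):
        idx = np.arange(start, min(start + batch_size, n))
        logits = model.forward(data.take(idx))
        out.append(1.0 / (1.0 + np.exp(-np.clip(logits.data.ravel(), -60, 60))))
    return np.concatenate(out) if out else np.array([])
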