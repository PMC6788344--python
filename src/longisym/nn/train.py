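"""Training loop: softmax cross-entropy, Adam, early stopping.

The loss is binary cross-entropy expressed over the 2-unit softmax head
with one-hot targets.  Training stops after a configurable number of
epochs without validation-loss improvement and restores the
best-validation weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ConfigurationError, TrainingError
from .model import DeepSymNetModel, _softmax

__all__ = ["TrainConfig", "Adam", "train"]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 4
    max_epochs: int = 150
    early_stop_patience: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.early_stop_patience < self.max_epochs:
            raise ConfigurationError("patience must be smaller than max_epochs")
        if self.batch_size < 1 or self.learning_rate < 0:
            raise ConfigurationError("invalid batch size or learning rate")


class Adam:
    """Adam optimizer over a model's named parameters."""

    def __init__(self, model: DeepSymNetModel, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in model.named_params().items()}
        self.v = {k: np.zeros_like(v) for k, v in model.named_params().items()}

    def step(self) -> None:
        self.t += 1
        params = self.model.named_params()
        grads = self.model.named_grads()
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            p -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def _stack(dataset: list[tuple[np.ndarray, np.ndarray, int]], idx: np.ndarray):
    x1 = np.stack([np.asarray(dataset[i][0], dtype=np.float32) for i in idx])
    x2 = np.stack([np.asarray(dataset[i][1], dtype=np.float32) for i in idx])
    y = np.asarray([int(dataset[i][2]) for i in idx])
    return x1, x2, y


def _ce_loss_and_grad(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    p = _softmax(z.astype(np.float64))
    n = len(y)
    onehot = np.zeros_like(p)
    onehot[np.arange(n), y] = 1.0
    loss = float(-np.mean(np.log(np.clip(p[np.arange(n), y], 1e-12, None))))
    return loss, ((p - onehot) / n).astype(np.float32)


def _eval_loss(model: DeepSymNetModel, dataset, idx: np.ndarray, batch_size: int) -> float:
    total, count = 0.0, 0
    for start in range(0, len(idx), batch_size):
        batch = idx[start : start + batch_size]
        x1, x2, y = _stack(dataset, batch)
        z, _ = model.forward_logits(x1, x2)
        loss, _ = _ce_loss_and_grad(z, y)
        total += loss * len(batch)
        count += len(batch)
    return total / count


def train(
    model: DeepSymNetModel,
    dataset: list[tuple[np.ndarray, np.ndarray, int]],
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    tc: TrainConfig = TrainConfig(),
) -> DeepSymNetModel:
    """Fit in place; returns the model with best-validation weights restored.

    ``dataset`` holds (session1, session2, label) triples with labels in
    {0, 1}; ``train_idx`` and ``val_idx`` must be disjoint and each contain
    both classes.
    """
    train_idx = np.asarray(train_idx, dtype=int)
    val_idx = np.asarray(val_idx, dtype=int)
    if set(train_idx) & set(val_idx):
        raise TrainingError("train and validation sets overlap")
    for name, idx in (("training", train_idx), ("validation", val_idx)):
        labels = {int(dataset[i][2]) for i in idx}
        if labels != {0, 1}:
            raise TrainingError(f"{name} set must contain both classes, got {labels}")

    rng = np.random.default_rng([tc.seed, 11])
    opt = Adam(model, tc.learning_rate)
    best_val = np.inf
    best_state = model.state_dict()
    epochs_since_best = 0
    model.training_history = []
    for epoch in range(1, tc.max_epochs + 1):
        order = rng.permutation(train_idx)
        epoch_loss, seen = 0.0, 0
        for start in range(0, len(order), tc.batch_size):
            batch = order[start : start + tc.batch_size]
            x1, x2, y = _stack(dataset, batch)
            model.zero_grads()
            z, cache = model.forward_logits(x1, x2)
            loss, gz = _ce_loss_and_grad(z, y)
            model.backward(gz, cache)
            opt.step()
            epoch_loss += loss * len(batch)
            seen += len(batch)
        val_loss = _eval_loss(model, dataset, val_idx, tc.batch_size)
        model.training_history.append(
            {"epoch": epoch, "train_loss": epoch_loss / seen, "val_loss": val_loss}
        )
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            epochs_since_best = 0
        else:
            epochs_since_best += 1
        if epochs_since_best >= tc.early_stop_patience:
            break
    model.load_state_dict(best_state)
    return model
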