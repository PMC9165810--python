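"""SGD training with momentum, cosine-annealed learning rate and
augmentation-in-the-loop.

The optimizer is plain SGD with momentum (v <- mu*v + g; w <- w - lr*v).
The learning rate follows a single cosine arc over ``t_max`` optimizer
iterations (no restarts), held at 0 afterwards.  Two-scale noise
augmentation is applied to training batches only — validation epochs pass
through normalization alone — and the spatial filters' max-norm cap is
re-projected after every step.  Model selection keeps the
best-validation-accuracy parameters, recorded alongside the final ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from residual_eegnet import nn
from residual_eegnet._rng import substream
from residual_eegnet.data_model import EEGEpoch, stack_epochs
from residual_eegnet.preprocessing import AugmentParams, augment_array, zscore_array

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    lr0: float = 0.001
    momentum: float = 0.9
    t_max: int = 29_000
    batch_size: int = 100
    epochs: int = 1000
    seed: int = 0
    zscore_scope: str = "per_channel"
    #: optional convergence shortcut: stop once validation accuracy reaches
    #: this level (None = run all epochs).
    early_stop_val_acc: float | None = None

    def __post_init__(self):
        if self.lr0 <= 0 or self.momentum < 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("invalid training configuration")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")


@dataclass
class TrainState:
    loss_trace: list[float] = field(default_factory=list)
    #: per-epoch accuracy of the training batches as seen during the pass
    #: (train mode, augmented inputs) — a cheap progress signal
    train_acc_trace: list[float] = field(default_factory=list)
    #: exact eval-mode accuracy on the training set of the final parameters
    final_train_accuracy: float = float("nan")
    val_acc_trace: list[float] = field(default_factory=list)
    lr_trace: list[float] = field(default_factory=list)
    step_trace: list[int] = field(default_factory=list)
    best_epoch: int = -1
    best_val_acc: float = float("nan")
    best_params: dict | None = None
    final_params: dict | None = None
    seed: int = 0
    n_train_augmented: int = 0
    n_val_augmented: int = 0

    @property
    def n_epochs_run(self) -> int:
        return len(self.loss_trace)


def cosine_lr(step: int, lr0: float, t_max: int) -> float:
    """Cosine-annealed learning rate, capped at ``t_max`` (no restarts)."""
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if step < 0:
        raise ValueError("step must be non-negative")
    frac = min(step, t_max) / t_max
    return lr0 * (1.0 + math.cos(math.pi * frac)) / 2.0


def loss_nll(log_scores: np.ndarray, labels) -> float:
    """Mean negative log-likelihood of the true labels (categorical
    cross-entropy on log-softmax scores)."""
    labels = np.asarray(labels, dtype=np.int64)
    if log_scores.shape[0] != labels.shape[0]:
        raise ValueError("log_scores and labels length mismatch")
    return float(-log_scores[np.arange(labels.size), labels].mean())


class SGD:
    """SGD with classical momentum and per-step max-norm re-projection."""

    def __init__(self, model: nn.Model, momentum: float):
        self.model = model
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.value) for p in model.parameters()]

    def step(self, lr: float) -> None:
        for p, v in zip(self.model.parameters(), self.velocity):
            v *= self.momentum
            v += p.grad
            p.value -= lr * v
        nn.apply_maxnorm(self.model)


def _accuracy(model: nn.Model, x: np.ndarray, y: np.ndarray,
              batch_size: int = 200) -> float:
    hits = 0
    for i in range(0, x.shape[0], batch_size):
        scores = model.forward(x[i : i + batch_size], train=False)
        hits += int((scores.argmax(axis=1) == y[i : i + batch_size]).sum())
    return hits / x.shape[0]


def prepare_arrays(epochs: list[EEGEpoch], scope: str = "per_channel",
                   dtype=np.float64):
    """Standardize and stack epochs into model-ready arrays."""
    x, y, subj = stack_epochs(epochs, dtype=dtype)
    for i in range(x.shape[0]):
        x[i, 0] = zscore_array(x[i, 0], scope=scope)
    return x, y, subj


def train_model(model: nn.Model, train_set: list[EEGEpoch],
                val_set: list[EEGEpoch], augment: AugmentParams,
                config: TrainConfig) -> TrainState:
    """Optimize ``model``; returns traces plus best/final parameters.

    Training and validation subject sets must be disjoint.  Batches are
    drawn by reshuffling the pooled training epochs every epoch;
    augmentation noise is fresh per batch.  Deterministic given
    ``config.seed``.  The model is left holding the best-validation
    parameters.
    """
    train_subj = {ep.subject_id for ep in train_set}
    val_subj = {ep.subject_id for ep in val_set}
    if train_subj & val_subj:
        raise ValueError(f"subject leakage between train and val: {train_subj & val_subj}")

    dtype = model.parameters()[0].value.dtype
    x_tr, y_tr, _ = prepare_arrays(train_set, config.zscore_scope, dtype)
    x_va, y_va, _ = prepare_arrays(val_set, config.zscore_scope, dtype)

    batch_rng = substream(config.seed, "batching")
    aug_rng = substream(config.seed, "augmentation")
    drop_rng = substream(config.seed, "init")  # dropout masks
    opt = SGD(model, config.momentum)
    state = TrainState(seed=config.seed)
    n = x_tr.shape[0]
    step = 0
    for epoch in range(config.epochs):
        order = batch_rng.permutation(n)
        losses = []
        batch_hits = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = x_tr[idx].copy()
            if augment.enabled:
                xb[:, 0] = augment_array(xb[:, 0], augment, aug_rng)
                state.n_train_augmented += len(idx)
            yb = y_tr[idx]
            scores = model.forward(xb, train=True, rng=drop_rng)
            loss = loss_nll(scores, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {step}: {loss}"
                )
            batch_hits += int((scores.argmax(axis=1) == yb).sum())
            g = np.zeros_like(scores)
            g[np.arange(yb.size), yb] = -1.0 / yb.size
            model.zero_grad()
            model.backward(g)
            lr = cosine_lr(step, config.lr0, config.t_max)
            opt.step(lr)
            state.lr_trace.append(lr)
            state.step_trace.append(step)
            losses.append(loss)
            step += 1
        state.loss_trace.append(float(np.mean(losses)))
        state.train_acc_trace.append(batch_hits / n)
        val_acc = _accuracy(model, x_va, y_va)
        state.val_acc_trace.append(val_acc)
        if state.best_params is None or val_acc > state.best_val_acc:
            state.best_val_acc = val_acc
            state.best_epoch = epoch
            state.best_params = model.state_dict()
        log.info(
            "epoch %d: loss %.4f train_acc %.3f val_acc %.3f lr %.2e",
            epoch, state.loss_trace[-1], state.train_acc_trace[-1], val_acc, lr,
        )
        if (config.early_stop_val_acc is not None
                and val_acc >= config.early_stop_val_acc):
            log.info("early stop: validation accuracy %.3f reached", val_acc)
            break
    state.final_params = model.state_dict()
    state.final_train_accuracy = _accuracy(model, x_tr, y_tr)
    model.load_state_dict(state.best_params)
    return state
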