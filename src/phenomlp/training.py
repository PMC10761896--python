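"""Mini-batch training with early stopping and best-model selection.

Each epoch shuffles the training cells (seeded), iterates batches of
``batch_size`` with dropout active, backpropagates the categorical
cross-entropy and takes an Adam step; validation loss is then evaluated with
dropout off. Training stops once at least ``min_epochs`` epochs have run and
the validation loss has not improved for ``patience`` epochs (or at
``max_epochs``); the parameters from the epoch with the lowest validation
loss are returned. UNASSIGNED cells are dropped from both sides unless
``include_unassigned`` is set and the vocabulary models them explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .classifier import (
    DEFAULT_HIDDEN_DIM,
    DropoutConfig,
    FeatureScaler,
    MLPParams,
    backward,
    forward,
    forward_cached,
    init_params,
)
from .core_data import CellTable, ClassVocabulary, EmptyTableError, UNASSIGNED

_PROB_FLOOR = 1e-12


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    batch_size 128 and dropout 0.25 are the defaults used across datasets;
    max_epochs is dataset-dependent (100 for a ~1M-cell table, 500 for
    smaller ones). min_epochs guarantees a floor of training; patience
    triggers early stopping when validation loss stalls.
    """

    batch_size: int = 128
    dropout_p: float = 0.25
    max_epochs: int = 100
    min_epochs: int = 10
    patience: int = 10
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    hidden_dim: int = DEFAULT_HIDDEN_DIM
    seed: int = 0
    include_unassigned: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.min_epochs <= self.max_epochs):
            raise ValueError("need 1 <= min_epochs <= max_epochs")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))


@dataclass
class TrainHistory:
    """Per-epoch losses and the early-stopping outcome (epochs 1-indexed)."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_macro_f1: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


class EarlyStopper:
    """Stop when epoch >= min_epochs and no improvement for >= patience epochs.

    ``update`` is called once per completed epoch with the validation loss
    and returns True when training should stop. Improvement is a strict
    decrease of the best seen loss.
    """

    def __init__(self, min_epochs: int, patience: int, max_epochs: int) -> None:
        self.min_epochs = min_epochs
        self.patience = patience
        self.max_epochs = max_epochs
        self.best_loss = np.inf
        self.best_epoch = 0
        self.epoch = 0

    def update(self, val_loss: float) -> bool:
        self.epoch += 1
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_epoch = self.epoch
        since_best = self.epoch - self.best_epoch
        if self.epoch >= self.max_epochs:
            return True
        return self.epoch >= self.min_epochs and since_best >= self.patience


def cross_entropy_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean over rows of -log(probability of the true class), floored at 1e-12."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=np.int64)
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= probs.shape[1]:
        raise ValueError("label index out of range")
    p = np.maximum(probs[np.arange(len(labels)), labels], _PROB_FLOOR)
    return float(-np.log(p).mean())


def _prepare(
    table: CellTable, vocab: ClassVocabulary, include_unassigned: bool, side: str
) -> tuple[np.ndarray, np.ndarray]:
    if not include_unassigned:
        table = table.labeled_subset()
    if table.n_cells == 0:
        raise EmptyTableError(f"{side} table empty after filtering UNASSIGNED cells")
    labels = table.labels
    if not include_unassigned and UNASSIGNED in labels:
        raise ValueError("internal: UNASSIGNED survived filtering")
    return table.features(), vocab.to_indices(labels)


class _Adam:
    def __init__(self, arrays: list[np.ndarray], lr: float) -> None:
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, arrays: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for a, g, m, v in zip(arrays, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            a -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _macro_f1_from_indices(y_true: np.ndarray, y_pred: np.ndarray, k: int) -> float:
    f1s = []
    for c in range(k):
        tp = np.sum((y_true == c) & (y_pred == c))
        fp = np.sum((y_true != c) & (y_pred == c))
        fn = np.sum((y_true == c) & (y_pred != c))
        denom = 2 * tp + fp + fn
        f1s.append(2 * tp / denom if denom else 0.0)
    return float(np.mean(f1s))


def fit(
    train: CellTable,
    val: CellTable,
    vocab: ClassVocabulary,
    config: TrainConfig,
) -> tuple[MLPParams, TrainHistory]:
    """Optimize MLP parameters on ``train``, selecting by validation loss."""
    train.check_labels(vocab)
    val.check_labels(vocab)
    x_tr, y_tr = _prepare(train, vocab, config.include_unassigned, "train")
    x_va, y_va = _prepare(val, vocab, config.include_unassigned, "validation")
    absent = [c for i, c in enumerate(vocab.classes) if i not in set(y_tr.tolist())]
    if absent:
        warnings.warn(
            f"vocabulary class(es) absent from training data: {', '.join(absent)}",
            stacklevel=2,
        )

    ss = np.random.SeedSequence(config.seed)
    init_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
    shuffle_rng, dropout_rng = (np.random.default_rng(s) for s in ss.spawn(3)[1:])

    params = init_params(x_tr.shape[1], len(vocab), config.hidden_dim, seed=init_seed)
    params.scaler = FeatureScaler.fit(x_tr)
    opt = _Adam(params.trainable_arrays(), config.learning_rate)
    dropout = DropoutConfig(p=config.dropout_p, active=True)
    stopper = EarlyStopper(config.min_epochs, config.patience, config.max_epochs)
    history = TrainHistory()
    best_params = params.copy()

    n = x_tr.shape[0]
    while True:
        order = shuffle_rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            probs, cache = forward_cached(x_tr[idx], params, dropout, dropout_rng)
            epoch_losses.append(cross_entropy_loss(probs, y_tr[idx]) * len(idx))
            grads = backward(probs, y_tr[idx], params, cache)
            opt.step(params.trainable_arrays(), grads)
        val_probs = forward(x_va, params)
        val_loss = cross_entropy_loss(val_probs, y_va)
        history.train_loss.append(float(np.sum(epoch_losses) / n))
        history.val_loss.append(val_loss)
        history.val_macro_f1.append(
            _macro_f1_from_indices(y_va, val_probs.argmax(axis=1), len(vocab))
        )
        improved = val_loss <= min(history.val_loss)
        stop = stopper.update(val_loss)
        if improved and stopper.best_epoch == stopper.epoch:
            best_params = params.copy()
        if stop:
            break
    history.best_epoch = stopper.best_epoch
    history.stopped_epoch = stopper.epoch
    return best_params, history


def subsample_training(
    table: CellTable,
    fraction: float,
    seed: int = 0,
    stratified: bool = False,
) -> CellTable:
    """Random sample without replacement of round(fraction * n) cells.

    With ``stratified`` the rounding applies per class (UNASSIGNED counts as
    its own stratum if present). fraction 1.0 returns the table unchanged.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1.0:
        return table
    rng = np.random.default_rng(seed)
    n = table.n_cells
    if stratified:
        labels = table.labels
        picks = []
        for c in sorted(set(labels.tolist())):
            idx = np.flatnonzero(labels == c)
            m = int(round(fraction * idx.size))
            picks.append(rng.choice(idx, size=m, replace=False))
        chosen = np.sort(np.concatenate(picks)) if picks else np.array([], dtype=int)
    else:
        m = int(round(fraction * n))
        chosen = np.sort(rng.choice(n, size=m, replace=False))
    if chosen.size == 0:
        raise EmptyTableError(f"subsample of fraction {fraction} is empty")
    return table.select(chosen)
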