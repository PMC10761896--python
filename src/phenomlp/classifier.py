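"""Feed-forward softmax classifier over per-cell marker expression.

The network takes x in R^(N+1) — a cell's N marker expressions plus its area
in pixels, standardized per feature — and passes it through four fully
connected hidden layers of width ``hidden_dim`` (512 by default):

    h_i = ReLU(W_i h_{i-1} + b_i),   i = 1..4,   h_0 = scaled x

followed by a classification layer whose softmax output is a probability
distribution over the K phenotypes; the predicted class is the argmax.
Dropout (inverted, so inference needs no rescaling) acts on each hidden
activation during training only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

N_HIDDEN_LAYERS = 4
DEFAULT_HIDDEN_DIM = 512
_SD_FLOOR = 1e-8


@dataclass
class DropoutConfig:
    """Dropout probability and whether it is active (training mode)."""

    p: float = 0.25
    active: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p < 1.0):
            raise ValueError(f"dropout probability must be in [0, 1), got {self.p}")


@dataclass
class FeatureScaler:
    """Per-feature standardization fitted on training data.

    scale is floored at 1e-8 so constant features do not divide by zero.
    """

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def identity(cls, dim: int) -> "FeatureScaler":
        return cls(np.zeros(dim), np.ones(dim))

    @classmethod
    def fit(cls, x: np.ndarray) -> "FeatureScaler":
        x = np.asarray(x, dtype=float)
        return cls(x.mean(axis=0), np.maximum(x.std(axis=0), _SD_FLOOR))

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.scale


@dataclass
class MLPParams:
    """Weights and biases of the four hidden layers and the classification
    layer, plus the fitted feature scaler.

    W[i] maps layer i-1 to layer i (shape in_dim x out_dim); Wc maps the last
    hidden layer to the K class logits.
    """

    input_dim: int
    hidden_dim: int
    n_classes: int
    W: list[np.ndarray]
    b: list[np.ndarray]
    Wc: np.ndarray
    bc: np.ndarray
    scaler: FeatureScaler = field(default_factory=lambda: FeatureScaler.identity(1))

    def __post_init__(self) -> None:
        if len(self.W) != N_HIDDEN_LAYERS or len(self.b) != N_HIDDEN_LAYERS:
            raise ValueError(f"expected {N_HIDDEN_LAYERS} hidden layers")
        dims = [self.input_dim] + [self.hidden_dim] * N_HIDDEN_LAYERS
        for i, (w, bias) in enumerate(zip(self.W, self.b)):
            if w.shape != (dims[i], dims[i + 1]) or bias.shape != (dims[i + 1],):
                raise ValueError(
                    f"layer {i + 1}: W shape {w.shape}, b shape {bias.shape} "
                    f"inconsistent with dims {dims[i]}->{dims[i + 1]}"
                )
        if self.Wc.shape != (self.hidden_dim, self.n_classes):
            raise ValueError(f"classification weights shape {self.Wc.shape}")
        if self.bc.shape != (self.n_classes,):
            raise ValueError(f"classification bias shape {self.bc.shape}")
        if (self.scaler.scale <= 0).any():
            raise ValueError("feature scaler scale must be positive")

    def copy(self) -> "MLPParams":
        return MLPParams(
            self.input_dim, self.hidden_dim, self.n_classes,
            [w.copy() for w in self.W], [b.copy() for b in self.b],
            self.Wc.copy(), self.bc.copy(),
            FeatureScaler(self.scaler.mean.copy(), self.scaler.scale.copy()),
        )

    def trainable_arrays(self) -> list[np.ndarray]:
        return [*self.W, *self.b, self.Wc, self.bc]


def init_params(
    input_dim: int,
    n_classes: int,
    hidden_dim: int = DEFAULT_HIDDEN_DIM,
    seed: int = 0,
) -> MLPParams:
    """Fan-in-scaled uniform weights (limit sqrt(6/fan_in)), zero biases,
    identity feature scaler until fitted."""
    if input_dim < 1 or n_classes < 1 or hidden_dim < 1:
        raise ValueError("dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    dims = [input_dim] + [hidden_dim] * N_HIDDEN_LAYERS
    W, b = [], []
    for i in range(N_HIDDEN_LAYERS):
        lim = np.sqrt(6.0 / dims[i])
        W.append(rng.uniform(-lim, lim, size=(dims[i], dims[i + 1])))
        b.append(np.zeros(dims[i + 1]))
    lim = np.sqrt(6.0 / hidden_dim)
    Wc = rng.uniform(-lim, lim, size=(hidden_dim, n_classes))
    bc = np.zeros(n_classes)
    return MLPParams(input_dim, hidden_dim, n_classes, W, b, Wc, bc,
                     FeatureScaler.identity(input_dim))


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, stabilized by subtracting the row maximum."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _check_input(x: np.ndarray, params: MLPParams) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != params.input_dim:
        raise ValueError(
            f"input has {x.shape[1]} features, expected {params.input_dim}"
        )
    if not np.isfinite(x).all():
        raise ValueError("input contains non-finite values")
    return x


def forward(
    x: np.ndarray,
    params: MLPParams,
    dropout: DropoutConfig | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Class-probability matrix for a batch of cells (rows sum to 1)."""
    probs, _ = forward_cached(x, params, dropout, rng)
    return probs


def forward_cached(
    x: np.ndarray,
    params: MLPParams,
    dropout: DropoutConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Forward pass retaining activations and dropout masks for backprop."""
    x = _check_input(x, params)
    dropout = dropout or DropoutConfig(active=False)
    if dropout.active and rng is None:
        raise ValueError("active dropout requires an rng")
    h = params.scaler.transform(x)
    cache: dict = {"h": [h], "mask": []}
    for W, b in zip(params.W, params.b):
        h = np.maximum(h @ W + b, 0.0)
        if dropout.active and dropout.p > 0.0:
            keep = rng.random(h.shape) >= dropout.p
            mask = keep / (1.0 - dropout.p)  # inverted dropout
            h = h * mask
        else:
            mask = None
        cache["h"].append(h)
        cache["mask"].append(mask)
    logits = h @ params.Wc + params.bc
    probs = softmax(logits)
    return probs, cache


def predict(
    x: np.ndarray, params: MLPParams, return_probs: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Argmax class index per row; ties break toward the lowest index."""
    probs = forward(x, params)
    idx = probs.argmax(axis=1)
    return (idx, probs) if return_probs else idx


def backward(
    probs: np.ndarray,
    labels: np.ndarray,
    params: MLPParams,
    cache: dict,
) -> list[np.ndarray]:
    """Gradients of mean cross-entropy w.r.t. trainable_arrays() order."""
    n = probs.shape[0]
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    h = cache["h"]
    dWc = h[-1].T @ dlogits
    dbc = dlogits.sum(axis=0)
    dh = dlogits @ params.Wc.T
    dW: list[np.ndarray] = [None] * N_HIDDEN_LAYERS  # type: ignore[list-item]
    db: list[np.ndarray] = [None] * N_HIDDEN_LAYERS  # type: ignore[list-item]
    for i in range(N_HIDDEN_LAYERS - 1, -1, -1):
        mask = cache["mask"][i]
        if mask is not None:
            dh = dh * mask
        dh = dh * (h[i + 1] > 0)  # ReLU gate (post-dropout activations > 0 iff kept)
        dW[i] = h[i].T @ dh
        db[i] = dh.sum(axis=0)
        dh = dh @ params.W[i].T
    return [*dW, *db, dWc, dbc]


# -- checkpointing ---------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(
    path: str | Path,
    params: MLPParams,
    markers: Sequence[str],
    classes: Sequence[str],
    train_config: dict | None = None,
) -> None:
    """Versioned container with all weights, the feature scaler, the marker
    list, the class vocabulary and the training configuration."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "input_dim": params.input_dim,
        "hidden_dim": params.hidden_dim,
        "n_classes": params.n_classes,
        "markers": list(markers),
        "classes": list(classes),
        "train_config": train_config or {},
    }
    arrays = {f"W{i}": w for i, w in enumerate(params.W)}
    arrays.update({f"b{i}": b for i, b in enumerate(params.b)})
    arrays.update(
        Wc=params.Wc, bc=params.bc,
        scaler_mean=params.scaler.mean, scaler_scale=params.scaler.scale,
    )
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path) -> tuple[MLPParams, dict]:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        params = MLPParams(
            meta["input_dim"], meta["hidden_dim"], meta["n_classes"],
            [z[f"W{i}"] for i in range(N_HIDDEN_LAYERS)],
            [z[f"b{i}"] for i in range(N_HIDDEN_LAYERS)],
            z["Wc"], z["bc"],
            FeatureScaler(z["scaler_mean"], z["scaler_scale"]),
        )
    return params, meta
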