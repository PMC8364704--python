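"""Small per-residue convolutional networks, trained with Adam.

Each feature set gets its own network mapping a residue's ``N_win x F``
feature matrix to a MoRF probability:

    conv(2x2, 16 filters, same padding, stride 1) -> activation
    -> conv(2x2, 8 filters, same padding, stride 1) -> activation
    -> 2x2 max-pool (stride 2, ceiling semantics)
    -> flatten -> fully connected (1 unit) -> sigmoid

For the default 3 x 16 input the shape trace is
3x16x16 -> 3x16x8 -> 2x8x8 -> 128 -> 1.  "Same" padding for the even
2x2 kernel adds one zero row/column at the bottom/right; pooling over
odd spatial dims pads with -inf so 3 pools to 2.

The implementation is plain numpy (forward, backprop, Adam, seeded
mini-batch shuffling), which keeps training bit-reproducible for a
fixed seed on a given platform.  Loss is binary cross-entropy with an
optional positive-class weight for imbalanced residue labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .features import ChannelStandardizer, ResidueFeatureMatrix

__all__ = [
    "CNNConfig",
    "TrainedCNN",
    "TrainingDivergedError",
    "build_model",
    "forward",
    "train",
    "predict_track",
    "save_model",
    "load_model",
]

_ACTIVATIONS = ("relu", "tanh", "sigmoid")


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class CNNConfig:
    """Architecture and optimization settings for one per-residue CNN.

    ``conv_filters`` gives the filter count of each 2x2 convolutional
    layer in order; the default ``(16, 8)`` is the two-layer reference
    architecture (ablation sweeps may use 3-4 layers).
    """

    input_shape: tuple[int, int] = (3, 16)
    conv_filters: tuple[int, ...] = (16, 8)
    hidden_activation: str = "relu"
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    batch_size: int = 128
    epochs: int = 30
    seed: int = 0
    positive_class_weight: float | None = None

    def __post_init__(self) -> None:
        if self.hidden_activation not in _ACTIVATIONS:
            raise ValueError(
                f"hidden_activation must be one of {_ACTIVATIONS}"
            )
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if len(self.conv_filters) < 1:
            raise ValueError("need at least one convolutional layer")
        if any(n < 1 for n in self.conv_filters):
            raise ValueError("filter counts must be >= 1")
        h, w = self.input_shape
        if h < 1 or w < 1:
            raise ValueError("input_shape entries must be >= 1")

    @property
    def pooled_shape(self) -> tuple[int, int]:
        h, w = self.input_shape
        return (-(-h // 2), -(-w // 2))  # ceil division

    @property
    def n_flat(self) -> int:
        ph, pw = self.pooled_shape
        return ph * pw * self.conv_filters[-1]


@dataclass
class TrainedCNN:
    """A (possibly untrained) CNN: config, parameters, and training state."""

    config: CNNConfig
    conv_weights: list[np.ndarray]  # each (out_ch, in_ch, 2, 2)
    conv_biases: list[np.ndarray]  # each (out_ch,)
    fc_weight: np.ndarray  # (n_flat,)
    fc_bias: float
    standardizer: ChannelStandardizer | None = None
    training_log: list[float] = field(default_factory=list)


def build_model(config: CNNConfig) -> TrainedCNN:
    """Initialize a CNN with He-scaled weights from a seeded stream."""
    rng = np.random.default_rng(config.seed)
    conv_w, conv_b = [], []
    in_ch = 1
    for out_ch in config.conv_filters:
        fan_in = in_ch * 4
        conv_w.append(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                 size=(out_ch, in_ch, 2, 2)))
        conv_b.append(np.zeros(out_ch))
        in_ch = out_ch
    fc_w = rng.normal(0.0, np.sqrt(1.0 / config.n_flat), size=config.n_flat)
    return TrainedCNN(config, conv_w, conv_b, fc_w, 0.0)


# ---------------------------------------------------------------------------
# forward / backward primitives


def _activate(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(z, 0.0)
    if kind == "tanh":
        return np.tanh(z)
    return _sigmoid(z)


def _activate_grad(z: np.ndarray, a: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return (z > 0.0).astype(z.dtype)
    if kind == "tanh":
        return 1.0 - a * a
    return a * (1.0 - a)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _conv2x2_same(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """2x2 convolution, stride 1, same padding (zero row/col bottom-right).

    x: (B, C, H, W); w: (O, C, 2, 2); returns (B, O, H, W).
    """
    B, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (0, 1), (0, 1)))
    out = np.zeros((B, w.shape[0], H, W))
    for p in (0, 1):
        for q in (0, 1):
            out += np.einsum(
                "bcij,oc->boij", xp[:, :, p : p + H, q : q + W], w[:, :, p, q]
            )
    return out + b[None, :, None, None]


def _conv2x2_backward(
    x: np.ndarray, w: np.ndarray, dz: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of a same-padded 2x2 conv: (dW, db, dx)."""
    B, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (0, 1), (0, 1)))
    dw = np.zeros_like(w)
    dxp = np.zeros_like(xp)
    for p in (0, 1):
        for q in (0, 1):
            patch = xp[:, :, p : p + H, q : q + W]
            dw[:, :, p, q] = np.einsum("boij,bcij->oc", dz, patch)
            dxp[:, :, p : p + H, q : q + W] += np.einsum(
                "boij,oc->bcij", dz, w[:, :, p, q]
            )
    db = dz.sum(axis=(0, 2, 3))
    return dw, db, dxp[:, :, :H, :W]


def _maxpool2x2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2x2 max-pool, stride 2, ceiling semantics via -inf padding.

    Returns (pooled, mask) where mask routes gradients back to the
    argmax cells (ties split evenly).
    """
    B, C, H, W = x.shape
    Hp, Wp = -(-H // 2) * 2, -(-W // 2) * 2
    xp = np.full((B, C, Hp, Wp), -np.inf)
    xp[:, :, :H, :W] = x
    blocks = xp.reshape(B, C, Hp // 2, 2, Wp // 2, 2)
    pooled = blocks.max(axis=(3, 5))
    mask = blocks == pooled[:, :, :, None, :, None]
    mask = mask / mask.sum(axis=(3, 5), keepdims=True)
    return pooled, mask


def _maxpool2x2_backward(
    dpool: np.ndarray, mask: np.ndarray, shape: tuple[int, ...]
) -> np.ndarray:
    B, C, H, W = shape
    dblocks = mask * dpool[:, :, :, None, :, None]
    dxp = dblocks.reshape(B, C, mask.shape[2] * 2, mask.shape[4] * 2)
    return dxp[:, :, :H, :W]


def _forward_batch(model: TrainedCNN, x: np.ndarray, need_cache: bool = False):
    """Forward pass on a batch of (B, N_win, F) matrices -> logits (B,)."""
    cfg = model.config
    a = x[:, None, :, :]  # (B, 1, H, W)
    cache = {"inputs": [], "zs": [], "acts": []}
    for w, b in zip(model.conv_weights, model.conv_biases):
        z = _conv2x2_same(a, w, b)
        act = _activate(z, cfg.hidden_activation)
        if need_cache:
            cache["inputs"].append(a)
            cache["zs"].append(z)
            cache["acts"].append(act)
        a = act
    pooled, mask = _maxpool2x2(a)
    flat = pooled.reshape(x.shape[0], -1)
    logits = flat @ model.fc_weight + model.fc_bias
    if need_cache:
        cache.update(pool_mask=mask, pre_pool_shape=a.shape, flat=flat)
        return logits, cache
    return logits


def _backward_batch(
    model: TrainedCNN, cache: dict, dlogits: np.ndarray
) -> dict[str, list | np.ndarray | float]:
    cfg = model.config
    dfc_w = cache["flat"].T @ dlogits
    dfc_b = float(dlogits.sum())
    dflat = np.outer(dlogits, model.fc_weight)
    B = dlogits.shape[0]
    ph, pw = cfg.pooled_shape
    dpool = dflat.reshape(B, cfg.conv_filters[-1], ph, pw)
    da = _maxpool2x2_backward(dpool, cache["pool_mask"], cache["pre_pool_shape"])
    dconv_w: list[np.ndarray] = []
    dconv_b: list[np.ndarray] = []
    for layer in range(len(model.conv_weights) - 1, -1, -1):
        z = cache["zs"][layer]
        act = cache["acts"][layer]
        dz = da * _activate_grad(z, act, cfg.hidden_activation)
        dw, db, da = _conv2x2_backward(
            cache["inputs"][layer], model.conv_weights[layer], dz
        )
        dconv_w.append(dw)
        dconv_b.append(db)
    return {
        "conv_w": dconv_w[::-1],
        "conv_b": dconv_b[::-1],
        "fc_w": dfc_w,
        "fc_b": dfc_b,
    }


# ---------------------------------------------------------------------------
# public operations


def forward(model: TrainedCNN, matrix: ResidueFeatureMatrix | np.ndarray) -> float:
    """Probability for a single residue's feature matrix."""
    m = matrix.matrix if isinstance(matrix, ResidueFeatureMatrix) else matrix
    m = np.asarray(m, dtype=float)
    if m.shape != model.config.input_shape:
        raise ValueError(
            f"matrix shape {m.shape} != config input {model.config.input_shape}"
        )
    if model.standardizer is not None:
        m = model.standardizer.transform(m[None])[0]
    logit = _forward_batch(model, m[None])[0]
    return float(_sigmoid(np.array([logit]))[0])


def predict_track(
    model: TrainedCNN, matrices: Sequence[ResidueFeatureMatrix] | np.ndarray
) -> np.ndarray:
    """Per-residue probabilities for a sequence's stack of feature matrices."""
    if isinstance(matrices, np.ndarray):
        x = np.asarray(matrices, dtype=float)
    else:
        x = np.stack([m.matrix for m in matrices])
    if x.ndim != 3 or x.shape[1:] != model.config.input_shape:
        raise ValueError(
            f"stack shape {x.shape} incompatible with input "
            f"{model.config.input_shape}"
        )
    if model.standardizer is not None:
        x = model.standardizer.transform(x)
    return _sigmoid(_forward_batch(model, x))


class _Adam:
    def __init__(self, cfg: CNNConfig, shapes: list[np.ndarray]):
        self.cfg = cfg
        self.m = [np.zeros_like(p) for p in shapes]
        self.v = [np.zeros_like(p) for p in shapes]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        c = self.cfg
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = c.beta1 * self.m[i] + (1 - c.beta1) * g
            self.v[i] = c.beta2 * self.v[i] + (1 - c.beta2) * g * g
            mhat = self.m[i] / (1 - c.beta1**self.t)
            vhat = self.v[i] / (1 - c.beta2**self.t)
            p -= c.learning_rate * mhat / (np.sqrt(vhat) + c.epsilon)


def train(
    model: TrainedCNN,
    x: np.ndarray,
    y: np.ndarray,
    standardizer: ChannelStandardizer | None = None,
) -> TrainedCNN:
    """Fit the CNN by seeded mini-batch Adam on binary cross-entropy.

    ``x`` is the (n, N_win, F) stack of (already standardized) feature
    matrices, ``y`` the 0/1 residue labels.  The shuffle order is drawn
    from the config seed, so identical (data, config, seed) reproduce
    identical parameters.  A fitted standardizer may be attached so
    prediction-time inputs are transformed with training statistics.
    """
    cfg = model.config
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y length mismatch")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")

    pos_w = cfg.positive_class_weight
    rng = np.random.default_rng(cfg.seed + 1)
    adam = _Adam(cfg, model.conv_weights + model.conv_biases
                 + [model.fc_weight, np.zeros(1)])
    n = x.shape[0]
    model.training_log = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            logits, cache = _forward_batch(model, xb, need_cache=True)
            probs = _sigmoid(logits)
            weights = np.ones_like(yb)
            if pos_w is not None:
                weights = np.where(yb == 1.0, pos_w, 1.0)
            # numerically stable BCE: softplus(logit) - y * logit
            loss_terms = np.logaddexp(0.0, logits) - yb * logits
            loss = float((weights * loss_terms).mean())
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch + 1}"
                )
            losses.append(loss * len(yb))
            dlogits = weights * (probs - yb) / len(yb)
            grads = _backward_batch(model, cache, dlogits)
            fc_b_holder = np.array([model.fc_bias])
            params = (model.conv_weights + model.conv_biases
                      + [model.fc_weight, fc_b_holder])
            glist = (grads["conv_w"] + grads["conv_b"]
                     + [grads["fc_w"], np.array([grads["fc_b"]])])
            adam.step(params, glist)
            model.fc_bias = float(fc_b_holder[0])
        model.training_log.append(sum(losses) / n)
    if standardizer is not None:
        model.standardizer = standardizer
    return model


# ---------------------------------------------------------------------------
# serialization (self-describing JSON archive)


def save_model(model: TrainedCNN, path: str | Path) -> None:
    doc = {
        "config": {
            "input_shape": list(model.config.input_shape),
            "conv_filters": list(model.config.conv_filters),
            "hidden_activation": model.config.hidden_activation,
            "learning_rate": model.config.learning_rate,
            "beta1": model.config.beta1,
            "beta2": model.config.beta2,
            "epsilon": model.config.epsilon,
            "batch_size": model.config.batch_size,
            "epochs": model.config.epochs,
            "seed": model.config.seed,
            "positive_class_weight": model.config.positive_class_weight,
        },
        "conv_weights": [w.tolist() for w in model.conv_weights],
        "conv_biases": [b.tolist() for b in model.conv_biases],
        "fc_weight": model.fc_weight.tolist(),
        "fc_bias": model.fc_bias,
        "standardizer": (
            model.standardizer.to_dict() if model.standardizer else None
        ),
        "training_log": model.training_log,
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> TrainedCNN:
    doc = json.loads(Path(path).read_text())
    c = doc["config"]
    config = CNNConfig(
        input_shape=tuple(c["input_shape"]),
        conv_filters=tuple(c["conv_filters"]),
        hidden_activation=c["hidden_activation"],
        learning_rate=c["learning_rate"],
        beta1=c["beta1"],
        beta2=c["beta2"],
        epsilon=c["epsilon"],
        batch_size=c["batch_size"],
        epochs=c["epochs"],
        seed=c["seed"],
        positive_class_weight=c["positive_class_weight"],
    )
    std = (
        ChannelStandardizer.from_dict(doc["standardizer"])
        if doc["standardizer"]
        else None
    )
    return TrainedCNN(
        config=config,
        conv_weights=[np.asarray(w) for w in doc["conv_weights"]],
        conv_biases=[np.asarray(b) for b in doc["conv_biases"]],
        fc_weight=np.asarray(doc["fc_weight"]),
        fc_bias=float(doc["fc_bias"]),
        standardizer=std,
        training_log=list(doc["training_log"]),
    )
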