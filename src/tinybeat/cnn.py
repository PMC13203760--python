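"""Compact 1D-CNN for three-class beat classification, in pure NumPy.

The canonical topology takes a (250, 1) normalised heartbeat and
propagates it through

    Conv1D(16, k=3, ReLU) -> (248, 16)
    MaxPool1D(2)          -> (124, 16)
    Conv1D(32, k=3, ReLU) -> (122, 32)
    Flatten               -> 3904
    Dense(64, ReLU)       -> 64
    Dense(3, Softmax)     -> 3 classes (N, V, S)

with batch normalization after each convolution and 20% dropout before
the output layer (both toggleable).  Convolutions are valid (no
padding), stride 1.  Training uses Adam on categorical cross-entropy
with early stopping on validation loss and best-weight restoration.

Everything is implemented here rather than delegated to a deep-learning
framework so the arithmetic is fully transparent to the quantizer and
the integer inference engine downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .containers import BeatDataset, N_CLASSES, SEGMENT_LENGTH

logger = logging.getLogger(__name__)

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


# ---------------------------------------------------------------------------
# Architecture description
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Architecture:
    """Topology descriptor.

    ``conv_filters``/``conv_kernels`` describe the convolution stack with a
    MaxPool(2) after every entry of ``pool_after`` (conv indices, 0-based).
    """

    input_length: int = SEGMENT_LENGTH
    conv_filters: tuple[int, ...] = (16, 32)
    conv_kernels: tuple[int, ...] = (3, 3)
    pool_after: tuple[int, ...] = (0,)
    dense_units: tuple[int, ...] = (64,)
    n_classes: int = N_CLASSES
    batch_norm_after_conv: bool = True
    dropout_rate: float = 0.2

    def propagate_shapes(self) -> list[tuple[int, ...]]:
        """Shapes after each block, ending with (flatten, dense..., classes)."""
        if len(self.conv_filters) != len(self.conv_kernels):
            raise ValueError("conv_filters and conv_kernels lengths differ")
        shapes: list[tuple[int, ...]] = []
        length, channels = self.input_length, 1
        for i, (f, k) in enumerate(zip(self.conv_filters, self.conv_kernels)):
            length = length - k + 1
            if length < 1:
                raise ValueError(f"conv {i} output length {length} < 1")
            channels = f
            shapes.append((length, channels))
            if i in self.pool_after:
                length = length // 2
                if length < 1:
                    raise ValueError(f"pool after conv {i} output length {length} < 1")
                shapes.append((length, channels))
        flat = length * channels
        shapes.append((flat,))
        for u in self.dense_units:
            shapes.append((u,))
        shapes.append((self.n_classes,))
        return shapes


def canonical_architecture(**overrides) -> Architecture:
    """The canonical topology above."""
    return replace(Architecture(), **overrides) if overrides else Architecture()


def reduced_architecture() -> Architecture:
    """A deliberately smaller preset (extra pool + 9-unit dense head).

    Provided for memory-constrained experiments; never the default.
    """
    return Architecture(pool_after=(0, 1), dense_units=(9,))


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults: lr 1e-3, batch 32, 100 epochs,
    Adam, categorical cross-entropy, early-stopping patience 10)."""

    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 100
    early_stopping_patience: int = 10
    dropout: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.epochs) <= 0:
            raise ValueError("learning_rate, batch_size and epochs must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.early_stopping_patience >= self.epochs:
            raise ValueError("patience must be < epochs")


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Layer:
    """Base layer: ``params``/``grads`` are parallel lists of arrays."""

    kind = "base"

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """Valid convolution, stride 1.  Weights shaped (k, in_ch, out_ch)."""

    kind = "conv"

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        limit = np.sqrt(6.0 / (kernel * in_ch + out_ch))  # Glorot uniform
        self.w = rng.uniform(-limit, limit, size=(kernel, in_ch, out_ch))
        self.b = np.zeros(out_ch)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        # x: (B, L, C) -> (B, L-k+1, F)
        self._x = x
        B, L, C = x.shape
        lout = L - self.kernel + 1
        cols = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=1)
        # cols: (B, lout, C, k) -> (B, lout, k*C) matching w.reshape(k*C, F)
        cols = cols.transpose(0, 1, 3, 2).reshape(B, lout, self.kernel * C)
        self._cols = cols
        return cols @ self.w.reshape(self.kernel * C, self.out_ch) + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, lout, F = dout.shape
        k, C = self.kernel, self.in_ch
        dw = np.einsum("blj,blf->jf", self._cols, dout).reshape(k, C, F)
        self.grads[0][...] = dw
        self.grads[1][...] = dout.sum(axis=(0, 1))
        dx = np.zeros_like(self._x)
        wf = self.w  # (k, C, F)
        for j in range(k):
            dx[:, j : j + lout, :] += dout @ wf[j].T
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalization over batch and time axes."""

    kind = "batchnorm"

    def __init__(self, channels: int):
        super().__init__()
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = _BN_MOMENTUM * self.running_mean + (1 - _BN_MOMENTUM) * mean
            self.running_var = _BN_MOMENTUM * self.running_var + (1 - _BN_MOMENTUM) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + _BN_EPS)
        self._xhat = (x - mean) / self._std
        self._axes = axes
        self._n = x.size // x.shape[-1]
        return self.gamma * self._xhat + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        axes, n = self._axes, self._n
        self.grads[0][...] = (dout * self._xhat).sum(axis=axes)
        self.grads[1][...] = dout.sum(axis=axes)
        dxhat = dout * self.gamma
        return (
            dxhat - dxhat.mean(axis=axes) - self._xhat * (dxhat * self._xhat).mean(axis=axes)
        ) / self._std


class ReLU(Layer):
    kind = "relu"

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling (pool=2); trailing odd sample dropped."""

    kind = "maxpool"

    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, L, C = x.shape
        lout = L // self.pool
        xw = x[:, : lout * self.pool, :].reshape(B, lout, self.pool, C)
        self._argmax = xw.argmax(axis=2)
        self._in_shape = x.shape
        return xw.max(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, lout, C = dout.shape
        dx = np.zeros(self._in_shape)
        dxw = dx[:, : lout * self.pool, :].reshape(B, lout, self.pool, C)
        b, l, c = np.ogrid[:B, :lout, :C]
        dxw[b, l, self._argmax, c] = dout
        return dx


class Flatten(Layer):
    kind = "flatten"

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    kind = "dense"

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.w = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.w.T


class Dropout(Layer):
    kind = "dropout"

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self._rng = rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0:
            return x
        self._mask = (self._rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class FloatModel:
    """Layered real-arithmetic model plus training history."""

    architecture: Architecture
    layers: list[Layer]
    seed: int
    history: dict[str, list[float]] = field(default_factory=dict)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits for a batch; ``x`` is (B, 250) or (B, 250, 1)."""
        if x.ndim == 2:
            x = x[:, :, None]
        if x.shape[1] != self.architecture.input_length:
            raise ValueError(
                f"expected segments of length {self.architecture.input_length}, got {x.shape[1]}"
            )
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend(p.copy() for p in layer.params)
            if isinstance(layer, BatchNorm):
                out.extend([layer.running_mean.copy(), layer.running_var.copy()])
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        i = 0
        for layer in self.layers:
            for p in layer.params:
                p[...] = weights[i]
                i += 1
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = weights[i]
                layer.running_var[...] = weights[i + 1]
                i += 2


def build_model(arch: Architecture | None = None, seed: int = 0) -> FloatModel:
    """Build the model with deterministic Glorot-uniform initialization."""
    arch = arch or canonical_architecture()
    shapes = arch.propagate_shapes()  # validates the topology
    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    channels = 1
    for i, (f, k) in enumerate(zip(arch.conv_filters, arch.conv_kernels)):
        layers.append(Conv1D(channels, f, k, rng))
        if arch.batch_norm_after_conv:
            layers.append(BatchNorm(f))
        layers.append(ReLU())
        if i in arch.pool_after:
            layers.append(MaxPool1D(2))
        channels = f
    layers.append(Flatten())
    n_in = shapes[len(shapes) - len(arch.dense_units) - 2][0]
    for u in arch.dense_units:
        layers.append(Dense(n_in, u, rng))
        layers.append(ReLU())
        n_in = u
    if arch.dropout_rate > 0:
        layers.append(Dropout(arch.dropout_rate, np.random.default_rng(seed + 1)))
    layers.append(Dense(n_in, arch.n_classes, rng))
    return FloatModel(architecture=arch, layers=layers, seed=seed)


def count_parameters(model: FloatModel) -> int:
    """Trainable parameter count (running BN statistics excluded)."""
    return int(sum(p.size for layer in model.layers for p in layer.params))


def predict_float(model: FloatModel, segments: np.ndarray) -> np.ndarray:
    """Per-class softmax probabilities, rows on the simplex."""
    segments = np.asarray(segments, dtype=np.float64)
    if segments.ndim == 1:
        segments = segments[None, :]
    return _softmax(model.forward(segments, training=False))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray], lr: float):
        self.params, self.grads, self.lr = params, grads, lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def _one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((y.size, n_classes))
    out[np.arange(y.size), y] = 1.0
    return out


def _evaluate(model: FloatModel, X: np.ndarray, y: np.ndarray, batch: int = 256):
    losses, correct = [], 0
    for i in range(0, len(X), batch):
        probs = _softmax(model.forward(X[i : i + batch], training=False))
        yy = y[i : i + batch]
        losses.append(-np.log(np.clip(probs[np.arange(len(yy)), yy], 1e-12, None)))
        correct += int((probs.argmax(axis=1) == yy).sum())
    return float(np.concatenate(losses).mean()), correct / len(X)


def train(
    model: FloatModel,
    ds_train: BeatDataset,
    ds_val: BeatDataset,
    cfg: TrainConfig | None = None,
) -> FloatModel:
    """Train in place with Adam + categorical cross-entropy.

    Early stopping monitors validation loss with the configured patience
    and restores the best-validation weights.  Fully deterministic for a
    fixed seed (single-threaded NumPy arithmetic).
    """
    cfg = cfg or TrainConfig()
    if len(ds_train) == 0 or len(ds_val) == 0:
        raise ValueError("training and validation datasets must be non-empty")
    present = set(np.unique(ds_train.y).tolist())
    if present != {0, 1, 2}:
        raise ValueError(f"training set must contain all three classes, has {sorted(present)}")

    for layer in model.layers:
        if isinstance(layer, Dropout):
            layer.rate = cfg.dropout
            layer._rng = np.random.default_rng(cfg.seed + 1)

    rng = np.random.default_rng(cfg.seed)
    params = [p for layer in model.layers for p in layer.params]
    grads = [g for layer in model.layers for g in layer.grads]
    opt = _Adam(params, grads, cfg.learning_rate)

    X, y = ds_train.X, ds_train.y
    Y = _one_hot(y, model.architecture.n_classes)
    history: dict[str, list[float]] = {k: [] for k in ("loss", "accuracy", "val_loss", "val_accuracy")}
    best_loss, best_weights, wait = np.inf, model.get_weights(), 0

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(X))
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, len(X), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            logits = model.forward(X[idx], training=True)
            probs = _softmax(logits)
            yy = y[idx]
            ep_loss += float(
                -np.log(np.clip(probs[np.arange(len(idx)), yy], 1e-12, None)).sum()
            )
            ep_correct += int((probs.argmax(axis=1) == yy).sum())
            dlogits = (probs - Y[idx]) / len(idx)
            for layer in reversed(model.layers):
                dlogits = layer.backward(dlogits)
            opt.step()
        val_loss, val_acc = _evaluate(model, ds_val.X, ds_val.y)
        history["loss"].append(ep_loss / len(X))
        history["accuracy"].append(ep_correct / len(X))
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(val_acc)
        logger.debug(
            "epoch %d: loss %.4f acc %.4f val_loss %.4f val_acc %.4f",
            epoch, history["loss"][-1], history["accuracy"][-1], val_loss, val_acc,
        )
        if val_loss < best_loss - 1e-6:
            best_loss, best_weights, wait = val_loss, model.get_weights(), 0
        else:
            wait += 1
            if wait >= cfg.early_stopping_patience:
                logger.info("early stopping at epoch %d (best val_loss %.4f)", epoch, best_loss)
                break

    model.set_weights(best_weights)
    model.history = history
    return model


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_float_model(model: FloatModel, path: str | Path) -> None:
    """Save architecture descriptor + per-layer tensors in one container."""
    arch = model.architecture
    meta = dict(
        input_length=arch.input_length,
        conv_filters=list(arch.conv_filters),
        conv_kernels=list(arch.conv_kernels),
        pool_after=list(arch.pool_after),
        dense_units=list(arch.dense_units),
        n_classes=arch.n_classes,
        batch_norm_after_conv=int(arch.batch_norm_after_conv),
        dropout_rate=arch.dropout_rate,
        seed=model.seed,
    )
    arrays = {f"w{i}": w for i, w in enumerate(model.get_weights())}
    for k, v in model.history.items():
        arrays[f"hist_{k}"] = np.asarray(v)
    np.savez(Path(path), meta=np.array([repr(meta)], dtype=object), **arrays)


def load_float_model(path: str | Path) -> FloatModel:
    with np.load(Path(path), allow_pickle=True) as z:
        meta = eval(str(z["meta"][0]), {"__builtins__": {}})  # trusted own container
        arch = Architecture(
            input_length=meta["input_length"],
            conv_filters=tuple(meta["conv_filters"]),
            conv_kernels=tuple(meta["conv_kernels"]),
            pool_after=tuple(meta["pool_after"]),
            dense_units=tuple(meta["dense_units"]),
            n_classes=meta["n_classes"],
            batch_norm_after_conv=bool(meta["batch_norm_after_conv"]),
            dropout_rate=meta["dropout_rate"],
        )
        model = build_model(arch, seed=meta["seed"])
        weights = [z[f"w{i}"] for i in range(len(model.get_weights()))]
        model.set_weights(weights)
        model.history = {
            k[len("hist_"):]: list(z[k]) for k in z.files if k.startswith("hist_")
        }
    return model
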