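"""Small convolutional binary classifiers, self-contained in NumPy.

Two architectures are provided for classifying encoded actigraphy images:

* ``simple``: [Conv2D(32, 5x5, same, ReLU) -> MaxPool(2x2)] x 2 ->
  Flatten -> Dense(256, ReLU) -> Dense(1, sigmoid)
* ``deep``:   [Conv2D(32, 5x5, same, ReLU) -> MaxPool(2x2) ->
  Dropout(0.5)] x 3 -> Flatten -> Dense(256, ReLU) -> Dropout(0.5) ->
  Dense(1, sigmoid)

Training minimizes binary cross-entropy with the Adam optimizer.  The
implementation is plain NumPy: convolutions are expressed as a sum of 25
BLAS matmuls (one per kernel offset), which keeps single-CPU training of
64x64 grayscale inputs fast enough for cohort-scale experiments.  All
randomness (weight init, shuffling, dropout) derives from ``config.seed``,
so training is reproducible on a single CPU thread.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ModelConfig",
    "TrainReport",
    "Model",
    "build_model",
    "train",
    "predict",
    "undersample_indices",
    "save_model",
    "load_model",
]


@dataclass
class ModelConfig:
    """Hyperparameters of the classifier."""

    variant: str = "simple"
    input_size: int = 64
    conv_filters: int = 32
    kernel_side: int = 5
    pool_side: int = 2
    dense_units: int = 256
    dropout_rate: float = 0.5
    learning_rate: float = 1e-3
    lr_decay: float = 0.85  # per-epoch multiplicative decay
    batch_size: int = 32
    epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ("simple", "deep"):
            raise ValueError("variant must be 'simple' or 'deep'")
        for name in ("input_size", "conv_filters", "kernel_side", "pool_side",
                     "dense_units", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 0.0 < self.lr_decay <= 1.0:
            raise ValueError("lr_decay must be in (0, 1]")
        if self.kernel_side % 2 == 0:
            raise ValueError("kernel_side must be odd for 'same' padding")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")

    @property
    def n_blocks(self) -> int:
        return 2 if self.variant == "simple" else 3


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Conv2D:
    """Same-padding 2-D convolution with ReLU-free linear output."""

    def __init__(self, rng: np.random.Generator, k: int, c_in: int, c_out: int):
        limit = np.sqrt(6.0 / (k * k * c_in + c_out))
        self.w = rng.uniform(-limit, limit, size=(k, k, c_in, c_out)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.k = k
        self._x_pad: np.ndarray | None = None

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def _im2col(self, x_pad: np.ndarray, n: int, h: int, w: int) -> np.ndarray:
        """Patch matrix of shape (n*h*w, k*k*c) for one big GEMM."""
        k = self.k
        c = x_pad.shape[-1]
        cols = np.empty((n, h, w, k * k, c), dtype=x_pad.dtype)
        for dy in range(k):
            for dx in range(k):
                cols[:, :, :, dy * k + dx, :] = x_pad[:, dy : dy + h, dx : dx + w, :]
        return cols.reshape(n * h * w, k * k * c)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k = self.k
        p = (k - 1) // 2
        n, h, w, c = x.shape
        x_pad = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        cols = self._im2col(x_pad, n, h, w)
        out = cols @ self.w.reshape(k * k * c, -1) + self.b
        self._cols = cols if train else None
        self._shape = (n, h, w, c)
        return out.reshape(n, h, w, -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k = self.k
        p = (k - 1) // 2
        n, h, w, c = self._shape
        c_out = dout.shape[-1]
        flat_dout = dout.reshape(-1, c_out)
        self.db[:] = flat_dout.sum(axis=0)
        self.dw[:] = (self._cols.T @ flat_dout).reshape(k, k, c, c_out)
        dcols = (flat_dout @ self.w.reshape(k * k * c, c_out).T).reshape(
            n, h, w, k * k, c
        )
        dx_pad = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=dout.dtype)
        for dy in range(k):
            for dx in range(k):
                dx_pad[:, dy : dy + h, dx : dx + w, :] += dcols[:, :, :, dy * k + dx, :]
        return dx_pad[:, p : p + h, p : p + w, :]


class _ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class _MaxPool:
    """Non-overlapping max pooling; trailing rows/cols are dropped."""

    def __init__(self, p: int):
        self.p = p

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        p = self.p
        n, h, w, c = x.shape
        hc, wc = (h // p) * p, (w // p) * p
        xr = x[:, :hc, :wc, :].reshape(n, hc // p, p, wc // p, p, c)
        out = xr.max(axis=(2, 4))
        if train:
            mask = xr == out[:, :, None, :, None, :]
            self._mask = mask
            self._counts = mask.sum(axis=(2, 4), keepdims=True)
            self._in_shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        p = self.p
        n, h, w, c = self._in_shape
        hc, wc = (h // p) * p, (w // p) * p
        dxr = self._mask * (dout[:, :, None, :, None, :] / self._counts)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, :hc, :wc, :] = dxr.reshape(n, hc, wc, c)
        return dx


class _Dropout:
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng_holder: dict):
        self.rate = rate
        self._rng_holder = rng_holder

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        rng = self._rng_holder["rng"]
        self._mask = (rng.random(x.shape) >= self.rate).astype(np.float32) / (
            1.0 - self.rate
        )
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class _Flatten:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class _Dense:
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.w = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x if train else None
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw[:] = self._x.T @ dout
        self.db[:] = dout.sum(axis=0)
        return dout @ self.w.T


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class Model:
    """A built (possibly trained) CNN: an ordered layer stack plus config."""

    config: ModelConfig
    layers: list = field(default_factory=list)
    dropout_rng_holder: dict = field(default_factory=dict)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits of shape (N,) for a batch (N, H, W, 1)."""
        out = x
        for layer in self.layers:
            out = layer.forward(out, train)
        return out[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        dout = dlogits[:, None]
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out


def build_model(config: ModelConfig) -> Model:
    """Construct the requested architecture with seeded weight init."""
    min_size = config.pool_side ** config.n_blocks
    if config.input_size < min_size:
        raise ValueError(
            f"input_size {config.input_size} too small for "
            f"{config.n_blocks} pooling stages; minimum is {min_size}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    holder = {"rng": np.random.default_rng(np.random.SeedSequence([config.seed, 1]))}
    layers: list = []
    side = config.input_size
    c_in = 1
    for _ in range(config.n_blocks):
        layers.append(_Conv2D(rng, config.kernel_side, c_in, config.conv_filters))
        layers.append(_ReLU())
        layers.append(_MaxPool(config.pool_side))
        if config.variant == "deep":
            layers.append(_Dropout(config.dropout_rate, holder))
        side //= config.pool_side
        c_in = config.conv_filters
    layers.append(_Flatten())
    layers.append(_Dense(rng, side * side * c_in, config.dense_units))
    layers.append(_ReLU())
    if config.variant == "deep":
        layers.append(_Dropout(config.dropout_rate, holder))
    layers.append(_Dense(rng, config.dense_units, 1))
    return Model(config=config, layers=layers, dropout_rng_holder=holder)


@dataclass
class TrainReport:
    """Per-epoch training history plus the trained model."""

    loss_history: list
    val_metrics: list
    final_model: Model
    config: ModelConfig


def _as_batch(images: np.ndarray) -> np.ndarray:
    x = np.asarray(images, dtype=np.float32)
    if x.ndim == 3:
        x = x[..., None]
    if x.ndim != 4 or x.shape[-1] != 1:
        raise ValueError("images must have shape (N, H, W) or (N, H, W, 1)")
    return x


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def train(
    model: Model,
    images: np.ndarray,
    labels: np.ndarray,
    config: ModelConfig | None = None,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> TrainReport:
    """Fit with Adam on binary cross-entropy.

    ``validation`` is an optional ``(images, labels)`` pair; per-epoch
    accuracy is computed on it when given, otherwise on the training set.
    Raises on a training set that does not contain at least two examples
    of each class.  ``epochs = 0`` returns an empty history and leaves the
    model untrained.
    """
    config = config or model.config
    x = _as_batch(images)
    y = np.asarray(labels, dtype=np.float32).ravel()
    if x.shape[0] != y.size:
        raise ValueError("images and labels length mismatch")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError(
            "training set must contain at least 2 examples of each class "
            f"(got {n_pos} positive, {n_neg} negative)"
        )
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    model.dropout_rng_holder["rng"] = np.random.default_rng(
        np.random.SeedSequence([config.seed, 1])
    )
    params = model.parameters()
    m_state = [np.zeros_like(p) for p, _ in params]
    v_state = [np.zeros_like(p) for p, _ in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    loss_history: list[float] = []
    val_metrics: list[float] = []
    for epoch in range(config.epochs):
        epoch_lr = config.learning_rate * config.lr_decay**epoch
        perm = shuffle_rng.permutation(x.shape[0])
        epoch_loss = 0.0
        for start in range(0, x.shape[0], config.batch_size):
            idx = perm[start : start + config.batch_size]
            xb, yb = x[idx], y[idx]
            z = model.forward(xb, train=True)
            # stable BCE-with-logits: softplus(z) - y*z, averaged
            loss = float(np.mean(np.logaddexp(0.0, z) - yb * z))
            epoch_loss += loss * idx.size
            dz = (_sigmoid(z) - yb).astype(np.float32) / np.float32(idx.size)
            model.backward(dz)
            step += 1
            lr_t = epoch_lr * np.sqrt(1.0 - beta2**step) / (1.0 - beta1**step)
            for (p, g), m, v in zip(params, m_state, v_state):
                m *= beta1
                m += (1.0 - beta1) * g
                v *= beta2
                v += (1.0 - beta2) * g * g
                p -= (lr_t * m / (np.sqrt(v) + eps)).astype(p.dtype)
        loss_history.append(epoch_loss / x.shape[0])
        if validation is not None:
            vx, vy = validation
            probs = predict(model, vx)
            acc = float(np.mean((probs >= 0.5) == (np.asarray(vy).ravel() == 1)))
        else:
            probs = predict(model, x)
            acc = float(np.mean((probs >= 0.5) == (y == 1)))
        val_metrics.append(acc)
    return TrainReport(
        loss_history=loss_history,
        val_metrics=val_metrics,
        final_model=model,
        config=config,
    )


def predict(model: Model, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Sigmoid probabilities in [0, 1]; hard labels are ``probs >= 0.5``."""
    x = _as_batch(images)
    if x.shape[1] != model.config.input_size or x.shape[2] != model.config.input_size:
        raise ValueError(
            f"images are {x.shape[1]}x{x.shape[2]}, model expects "
            f"{model.config.input_size}x{model.config.input_size}"
        )
    probs = np.empty(x.shape[0], dtype=np.float64)
    for start in range(0, x.shape[0], batch_size):
        z = model.forward(x[start : start + batch_size], train=False)
        probs[start : start + batch_size] = _sigmoid(z.astype(np.float64))
    return probs


def undersample_indices(labels: np.ndarray, seed: int) -> np.ndarray:
    """Leakage-safe class rebalancing: random-undersample the majority class.

    Returns sorted indices of a balanced subset; apply to the *training*
    split only.
    """
    y = np.asarray(labels).ravel()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present to rebalance")
    k = min(pos.size, neg.size)
    keep = np.concatenate(
        [rng.choice(pos, size=k, replace=False), rng.choice(neg, size=k, replace=False)]
    )
    return np.sort(keep)


def save_model(model: Model, path: str | Path) -> Path:
    """Persist weights as an .npz archive (config stored as JSON sidecar-style)."""
    import json

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for i, (p, _) in enumerate(model.parameters()):
        arrays[f"param_{i}"] = p
    np.savez(path, **arrays)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(model.config.__dict__, indent=2, sort_keys=True))
    return path


def load_model(path: str | Path) -> Model:
    """Rebuild a model from :func:`save_model` output."""
    import json

    path = Path(path)
    config = ModelConfig(**json.loads(path.with_suffix(".json").read_text()))
    model = build_model(config)
    with np.load(path) as data:
        for i, (p, _) in enumerate(model.parameters()):
            p[:] = data[f"param_{i}"]
    return model
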