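"""Small convolutional classifier with channel boosting and layer freezing.

The classifier ("CBTCNNOD-small") is a deliberately compact CNN — three
convolution + downsample blocks, global average pooling, and a dense
softmax head — sized to train in CPU minutes on 64x64 multi-channel
texture stacks.  A feature map at layer l is the activation produced by
convolving the (boosted) input with that layer's kernel bank:
G_l = activation(I_B * k_l).

Transfer learning follows the freeze/fine-tune protocol: a model is first
trained on a source task; on the target task the initial ``freeze_upto``
parameterised blocks are frozen (their parameters are never touched, and
remain byte-identical) while the remaining blocks are trained.

Everything is plain numpy: deterministic given the seed, no GPU, no
framework.  Optimisation is minibatch SGD on the softmax cross-entropy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .boosting import AuxiliaryLearner, ChannelStack, boost
from .synthetic import LabelledDataset

__all__ = [
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "GlobalAvgPool",
    "Dense",
    "NetworkModel",
    "TrainConfig",
    "build_model",
    "pretrain",
    "transfer_and_finetune",
    "predict",
    "predict_proba",
    "prepare_inputs",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Layer:
    """Forward/backward node.  Parameterised layers carry a frozen flag."""

    frozen: bool = False

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def copy(self) -> "Layer":
        raise NotImplementedError


class Conv2D(Layer):
    """Same-padded 2-D convolution, kernels (kh, kw, C_in, C_out)."""

    def __init__(self, W: np.ndarray, b: np.ndarray):
        self.W = np.asarray(W, dtype=np.float64)
        self.b = np.asarray(b, dtype=np.float64)
        if self.W.ndim != 4 or self.b.shape != (self.W.shape[3],):
            raise ValueError("W must be (kh, kw, C_in, C_out), b (C_out,)")
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x_pad: np.ndarray | None = None

    @classmethod
    def init(cls, kh: int, kw: int, c_in: int, c_out: int, rng: np.random.Generator) -> "Conv2D":
        # He initialisation for ReLU-activated layers
        std = np.sqrt(2.0 / (kh * kw * c_in))
        return cls(rng.normal(0.0, std, size=(kh, kw, c_in, c_out)), np.zeros(c_out))

    def params(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}

    def grads(self) -> dict[str, np.ndarray]:
        return {"W": self.dW, "b": self.db}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        kh, kw, c_in, c_out = self.W.shape
        if x.shape[3] != c_in:
            raise ValueError(f"expected {c_in} input channels, got {x.shape[3]}")
        ph, pw = kh // 2, kw // 2
        x_pad = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        n, h, w, _ = x.shape
        out = np.broadcast_to(self.b, (n, h, w, c_out)).copy()
        for dy in range(kh):
            for dx in range(kw):
                out += x_pad[:, dy : dy + h, dx : dx + w, :] @ self.W[dy, dx]
        if train:
            self._x_pad = x_pad
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        kh, kw, c_in, c_out = self.W.shape
        x_pad = self._x_pad
        assert x_pad is not None, "backward before forward(train=True)"
        n, h, w, _ = dout.shape
        ph, pw = kh // 2, kw // 2
        self.db = dout.sum(axis=(0, 1, 2))
        dx_pad = np.zeros_like(x_pad)
        for dy in range(kh):
            for dx in range(kw):
                patch = x_pad[:, dy : dy + h, dx : dx + w, :]
                self.dW[dy, dx] = np.einsum("nhwc,nhwo->co", patch, dout, optimize=True)
                dx_pad[:, dy : dy + h, dx : dx + w, :] += dout @ self.W[dy, dx].T
        return dx_pad[:, ph : ph + h, pw : pw + w, :]

    def copy(self) -> "Conv2D":
        c = Conv2D(self.W.copy(), self.b.copy())
        c.frozen = self.frozen
        return c


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def copy(self) -> "ReLU":
        return ReLU()


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (even spatial dims required)."""

    def __init__(self) -> None:
        self._argmax: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {(h, w)}")
        windows = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        flat = windows.reshape(n, h // 2, w // 2, 4, c)
        if train:
            self._argmax = flat.argmax(axis=3)
            self._shape = x.shape
        return flat.max(axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h2, w2, c = dout.shape
        flat = np.zeros((n, h2, w2, 4, c), dtype=dout.dtype)
        np.put_along_axis(flat, self._argmax[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        return (
            flat.reshape(n, h2, w2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(self._shape)
        )

    def copy(self) -> "MaxPool2":
        return MaxPool2()


class GlobalAvgPool(Layer):
    def __init__(self) -> None:
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        return np.broadcast_to(dout[:, None, None, :] / (h * w), self._shape).copy()

    def copy(self) -> "GlobalAvgPool":
        return GlobalAvgPool()


class Dense(Layer):
    def __init__(self, W: np.ndarray, b: np.ndarray):
        self.W = np.asarray(W, dtype=np.float64)
        self.b = np.asarray(b, dtype=np.float64)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    @classmethod
    def init(cls, n_in: int, n_out: int, rng: np.random.Generator) -> "Dense":
        std = np.sqrt(2.0 / n_in)
        return cls(rng.normal(0.0, std, size=(n_in, n_out)), np.zeros(n_out))

    def params(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}

    def grads(self) -> dict[str, np.ndarray]:
        return {"W": self.dW, "b": self.db}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def copy(self) -> "Dense":
        d = Dense(self.W.copy(), self.b.copy())
        d.frozen = self.frozen
        return d


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

_LAYER_TYPES = {
    "Conv2D": Conv2D,
    "ReLU": ReLU,
    "MaxPool2": MaxPool2,
    "GlobalAvgPool": GlobalAvgPool,
    "Dense": Dense,
}


@dataclass
class NetworkModel:
    """Ordered layer list plus input/class metadata.

    ``blocks`` indexes the *parameterised* layers (convolutions and the
    dense head); the freeze protocol counts in blocks.
    """

    layers: list[Layer]
    input_spec: tuple[int, int, int]
    classes: tuple[str, ...]

    @property
    def blocks(self) -> list[Layer]:
        return [l for l in self.layers if l.params()]

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def n_parameters(self) -> int:
        return sum(p.size for l in self.layers for p in l.params().values())

    def parameter_vector(self) -> np.ndarray:
        """All parameters flattened, in layer order (for exact comparison)."""
        parts = [p.ravel() for l in self.layers for p in l.params().values()]
        return np.concatenate(parts) if parts else np.array([])

    def copy(self) -> "NetworkModel":
        return NetworkModel(
            layers=[l.copy() for l in self.layers],
            input_spec=self.input_spec,
            classes=self.classes,
        )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def set_freeze(self, freeze_upto: int) -> None:
        if not 0 <= freeze_upto <= self.n_blocks:
            raise ValueError(f"freeze_upto must be in [0, {self.n_blocks}], got {freeze_upto}")
        for i, block in enumerate(self.blocks):
            block.frozen = i < freeze_upto


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters; ``seed`` fixes initialisation and shuffling."""

    epochs: int = 12
    batch_size: int = 16
    learning_rate: float = 0.05
    seed: int = 0
    freeze_upto: int = 0
    validation_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training hyperparameters")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in [0, 1)")


def build_model(
    input_spec: tuple[int, int, int],
    classes: Sequence[str],
    seed: int = 0,
    widths: tuple[int, int, int] = (8, 16, 32),
) -> NetworkModel:
    """CBTCNNOD-small: 3 conv+pool blocks, global average pool, dense softmax.

    Initialisation is a pure function of ``seed``.  The spatial dims must
    be divisible by 8 (three 2x2 poolings).
    """
    h, w, c = input_spec
    if c < 1:
        raise ValueError("need at least one input channel")
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if h % 8 or w % 8:
        raise ValueError(f"spatial dims must be divisible by 8, got {(h, w)}")
    rng = np.random.default_rng(int(seed))
    w1, w2, w3 = widths
    layers: list[Layer] = [
        Conv2D.init(3, 3, c, w1, rng),
        ReLU(),
        MaxPool2(),
        Conv2D.init(3, 3, w1, w2, rng),
        ReLU(),
        MaxPool2(),
        Conv2D.init(3, 3, w2, w3, rng),
        ReLU(),
        MaxPool2(),
        GlobalAvgPool(),
        Dense.init(w3, len(classes), rng),
    ]
    return NetworkModel(layers=layers, input_spec=(h, w, c), classes=tuple(classes))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _encode_labels(labels: Sequence[str], classes: Sequence[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    try:
        return np.array([index[l] for l in labels], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"label {exc} not among model classes {tuple(classes)}") from exc


def prepare_inputs(
    dataset: LabelledDataset,
    learners: Sequence[AuxiliaryLearner],
    classes: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Boost every image and encode labels; returns (X, y, classes)."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    X = np.stack([boost(img, learners).channels for img in dataset.images], axis=0)
    classes = tuple(classes) if classes is not None else dataset.classes
    y = _encode_labels(dataset.labels, classes)
    return X, y, classes


def _train(
    model: NetworkModel,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
    freeze_upto: int,
) -> tuple[NetworkModel, list[dict[str, float]]]:
    if X.shape[0] == 0:
        raise ValueError("empty dataset")
    if X.shape[1:] != model.input_spec:
        raise ValueError(f"input shape {X.shape[1:]} != model spec {model.input_spec}")
    out = model.copy()
    out.set_freeze(freeze_upto)
    rng = np.random.default_rng(int(config.seed))
    n = X.shape[0]
    log: list[dict[str, float]] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        correct = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X[idx], y[idx]
            logits = out.forward(xb, train=True)
            probs = _softmax(logits)
            eps = 1e-12
            epoch_loss += -np.log(probs[np.arange(len(yb)), yb] + eps).sum()
            correct += int((probs.argmax(axis=1) == yb).sum())
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            grad = dlogits
            for layer in reversed(out.layers):
                grad = layer.backward(grad)
            for layer in out.layers:
                if layer.params() and not layer.frozen:
                    for name, p in layer.params().items():
                        p -= config.learning_rate * layer.grads()[name]
        log.append(
            {"epoch": epoch, "loss": epoch_loss / n, "accuracy": correct / n}
        )
    return out, log


def pretrain(
    model: NetworkModel,
    dataset: LabelledDataset | tuple[np.ndarray, np.ndarray],
    config: TrainConfig,
    learners: Sequence[AuxiliaryLearner] = (),
) -> tuple[NetworkModel, list[dict[str, float]]]:
    """Train all layers on the (source) task from the given initialisation."""
    if isinstance(dataset, LabelledDataset):
        X, y, _ = prepare_inputs(dataset, learners, classes=model.classes)
    else:
        X, y = dataset
    return _train(model, X, y, config, freeze_upto=0)


def transfer_and_finetune(
    model: NetworkModel,
    target_dataset: LabelledDataset | tuple[np.ndarray, np.ndarray],
    config: TrainConfig,
    learners: Sequence[AuxiliaryLearner] = (),
) -> tuple[NetworkModel, list[dict[str, float]]]:
    """Fine-tune on the target task with the first ``config.freeze_upto``
    parameterised blocks frozen; frozen parameters are returned bit-identical."""
    if isinstance(target_dataset, LabelledDataset):
        X, y, _ = prepare_inputs(target_dataset, learners, classes=model.classes)
    else:
        X, y = target_dataset
    return _train(model, X, y, config, freeze_upto=config.freeze_upto)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def predict_proba(model: NetworkModel, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Class probabilities for a batch of stacks (n, h, w, C)."""
    if X.shape[1:] != model.input_spec:
        raise ValueError(f"input shape {X.shape[1:]} != model spec {model.input_spec}")
    outs = [
        _softmax(model.forward(X[i : i + batch_size]))
        for i in range(0, X.shape[0], batch_size)
    ]
    return np.concatenate(outs, axis=0)


def predict(model: NetworkModel, stack: ChannelStack) -> dict[str, float]:
    """Per-class probabilities for one boosted input."""
    probs = predict_proba(model, stack.channels[None, ...])
    return {c: float(p) for c, p in zip(model.classes, probs[0])}


def predict_labels(model: NetworkModel, X: np.ndarray) -> list[str]:
    probs = predict_proba(model, X)
    return [model.classes[i] for i in probs.argmax(axis=1)]


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_model(model: NetworkModel, path: str | Path) -> None:
    """Single-file .npz checkpoint: parameters, layer spec, classes, freeze mask."""
    spec = {
        "input_spec": list(model.input_spec),
        "classes": list(model.classes),
        "layers": [type(l).__name__ for l in model.layers],
        "frozen": [bool(l.frozen) for l in model.layers],
    }
    arrays: dict[str, np.ndarray] = {}
    for i, layer in enumerate(model.layers):
        for name, p in layer.params().items():
            arrays[f"layer{i}_{name}"] = p
    np.savez(path, _spec=np.frombuffer(json.dumps(spec).encode(), dtype=np.uint8), **arrays)


def load_model(path: str | Path) -> NetworkModel:
    with np.load(path) as data:
        spec = json.loads(bytes(data["_spec"]).decode())
        layers: list[Layer] = []
        for i, lname in enumerate(spec["layers"]):
            cls = _LAYER_TYPES[lname]
            if lname == "Conv2D" or lname == "Dense":
                layer = cls(data[f"layer{i}_W"], data[f"layer{i}_b"])
            else:
                layer = cls()
            layer.frozen = spec["frozen"][i]
            layers.append(layer)
    return NetworkModel(
        layers=layers,
        input_spec=tuple(spec["input_spec"]),
        classes=tuple(spec["classes"]),
    )
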