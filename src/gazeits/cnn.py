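"""CNN models for image-panel classification: SimpleNet and AlexNet.

Both nets consume the 12-channel stack of per-trial transform images
(channels ordered MTF, GASF, GADF x left/right x X/Y).  SimpleNet is the
small net: two 5x5 convolutions (32 channels each, valid padding), two 2x2
max-pools, fully connected layers of 512 and 4 units with dropout in
between, and a 2-unit output — 1,364,942 learnable parameters at the
default 48x48 image size.  AlexNet is the classical 5-conv / 3-pool /
3-FC architecture adapted to the 12-channel input and 2 output units,
trained from scratch: 57,081,730 parameters (about 41x SimpleNet).

Training minimizes softmax cross-entropy with Adam and is bit-reproducible
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (Adam, AdaptiveAvgPool2d, Conv2d, Dropout, Flatten, Layer,
                 Linear, MaxPool2d, ReLU, Sequential, softmax_cross_entropy)

__all__ = [
    "TrainConfig",
    "build_simplenet",
    "build_alexnet",
    "train_cnn",
    "CNNClassifier",
]


class ShapeError(ValueError):
    pass


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    dropout: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size) < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size, learning_rate must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


def build_simplenet(input_shape: tuple[int, int, int] = (12, 48, 48),
                    n_classes: int = 2, dropout: float = 0.5,
                    seed: int = 0) -> Sequential:
    """SimpleNet: conv5(32) - pool2 - conv5(32) - pool2 - FC512 - FC4 - out.

    Valid padding when the spatial size allows (it does for 24-48 px
    images); below that the convolutions pad to keep the net well-defined.
    Raises ``ShapeError`` for inputs the net cannot consume.
    """
    c, h, w = input_shape
    rng = np.random.default_rng(seed)
    pad = 0
    if min(h, w) < 16:  # valid path needs ((s-4)/2 - 4) >= 2
        pad = 2
    conv1 = Conv2d(c, 32, 5, padding=pad, rng=rng)
    conv2 = Conv2d(32, 32, 5, padding=pad, rng=rng)
    h1, w1 = conv1.out_shape(h, w)
    h1, w1 = h1 // 2, w1 // 2
    h2, w2 = conv2.out_shape(h1, w1)
    h2, w2 = h2 // 2, w2 // 2
    if h2 < 1 or w2 < 1:
        raise ShapeError(f"input {input_shape} too small for SimpleNet")
    flat = 32 * h2 * w2
    return Sequential([
        conv1, ReLU(), MaxPool2d(2),
        conv2, ReLU(), MaxPool2d(2),
        Flatten(),
        Linear(flat, 512, rng=rng), ReLU(),
        Dropout(dropout, rng=np.random.default_rng(seed + 1)),
        # the 4-unit layer is a linear low-rank projection: a ReLU on so few
        # units is prone to permanent dead-unit collapse at this data scale
        Linear(512, 4, rng=rng),
        Linear(4, n_classes, rng=rng),
    ])


def build_alexnet(n_classes: int = 2, in_channels: int = 12,
                  dropout: float = 0.5, seed: int = 0) -> Sequential:
    """AlexNet (5 conv, 3 max-pool, 3 FC) for the 12-channel panel stack.

    Adaptive average pooling to 6x6 before the classifier makes the
    parameter count independent of the input side (which must be at least
    63 px for the pooling chain; upscale panels accordingly).
    """
    rng = np.random.default_rng(seed)
    drng = np.random.default_rng(seed + 1)
    return Sequential([
        Conv2d(in_channels, 64, 11, stride=4, padding=2, rng=rng), ReLU(),
        MaxPool2d(3, 2),
        Conv2d(64, 192, 5, padding=2, rng=rng), ReLU(),
        MaxPool2d(3, 2),
        Conv2d(192, 384, 3, padding=1, rng=rng), ReLU(),
        Conv2d(384, 256, 3, padding=1, rng=rng), ReLU(),
        Conv2d(256, 256, 3, padding=1, rng=rng), ReLU(),
        MaxPool2d(3, 2),
        AdaptiveAvgPool2d((6, 6)),
        Flatten(),
        Dropout(dropout, rng=drng),
        Linear(256 * 6 * 6, 4096, rng=rng), ReLU(),
        Dropout(dropout, rng=drng),
        Linear(4096, 4096, rng=rng), ReLU(),
        Linear(4096, n_classes, rng=rng),
    ])


def train_cnn(model: Sequential, panels: np.ndarray, labels: np.ndarray,
              config: TrainConfig | None = None) -> list[float]:
    """Train in place; returns the per-epoch mean loss trajectory."""
    config = config or TrainConfig()
    x = np.asarray(panels, dtype=np.float32)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=config.learning_rate)
    n = len(x)
    losses: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            scores = model.forward(x[idx], train=True)
            loss, grad = softmax_cross_entropy(scores, y[idx])
            model.backward(grad)
            opt.step()
            epoch_loss += loss * len(idx)
        losses.append(epoch_loss / n)
    return losses


class CNNClassifier:
    """sklearn-like wrapper so CNNs drop into the evaluation protocols.

    ``architecture`` is "simplenet" or "alexnet"; input is the (N, 12, s, s)
    panel stack.  Binary labels are mapped to class indices internally.
    """

    def __init__(self, architecture: str = "simplenet",
                 train_config: TrainConfig | None = None, seed: int = 0):
        self.architecture = architecture
        self.train_config = train_config or TrainConfig()
        self.seed = seed
        self.model_: Sequential | None = None
        self.classes_: np.ndarray | None = None
        self.losses_: list[float] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CNNClassifier":
        X = np.asarray(X, dtype=np.float32)
        self.classes_ = np.unique(y)
        y_idx = np.searchsorted(self.classes_, y)
        cfg = self.train_config
        if self.architecture == "simplenet":
            self.model_ = build_simplenet(X.shape[1:], len(self.classes_),
                                          dropout=cfg.dropout, seed=self.seed)
        elif self.architecture == "alexnet":
            self.model_ = build_alexnet(len(self.classes_), X.shape[1],
                                        dropout=cfg.dropout, seed=self.seed)
        else:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        self.losses_ = train_cnn(self.model_, X, y_idx, cfg)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_scores(X)
        return self.classes_[scores.argmax(axis=1)]

    def decision_scores(self, X: np.ndarray, batch: int = 64) -> np.ndarray:
        if self.model_ is None:
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=np.float32)
        outs = [self.model_.forward(X[i:i + batch], train=False)
                for i in range(0, len(X), batch)]
        return np.concatenate(outs)

    def get_params(self, deep: bool = True) -> dict:
        return {"architecture": self.architecture,
                "train_config": self.train_config, "seed": self.seed}

    def set_params(self, **kw) -> "CNNClassifier":
        for k, v in kw.items():
            setattr(self, k, v)
        return self
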