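"""The two-branch tabular+image FHR classifier.

Three architectures are provided:

* **MLP branch** — 15 -> 500 -> 250 -> 150 -> 50 -> 2 rectifier network over
  the normalized feature vector, with 0.4 dropout after hidden layers 1, 2
  and 4 and L1 = 1e-5 / L2 = 1e-4 kernel penalties on hidden layer 3.
* **CNN branch** — two valid-padding conv blocks (16 then 32 filters of
  5 x 5, each batch-normalized, 2 x 2 max-pooled) over the 64 x 64 x n image
  stack, 0.8 dropout, a 64-unit batch-normalized dense layer with 0.8
  dropout, a 16-unit dense layer, and a 2-way softmax.  The no-padding
  arithmetic gives 64 -> 60 -> 30 -> 26 -> 13, so the flatten width is
  13 * 13 * 32 = 5408.
* **Combined model** — the two branches' terminal 2-unit softmax outputs
  concatenated (4 fusion inputs) into a 128-unit rectifier layer and a
  2-way softmax.  A configuration switch fuses the penultimate layers
  (50 + 16 = 66 units) instead.

Training uses Adam (lr 1e-4, decay 1e-4/200), categorical cross-entropy on
the 2-way softmax (identical to binary cross-entropy for two classes), and
early stopping with patience 2 on a stratified 10% validation split of the
training data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from . import nn

__all__ = [
    "MLPSpec",
    "CNNSpec",
    "CombinedSpec",
    "TrainingConfig",
    "build",
    "build_mlp",
    "build_cnn",
    "build_combined",
    "train",
    "predict_proba",
]


@dataclass
class MLPSpec:
    """Topology of the tabular branch."""

    n_features: int = 15
    hidden: tuple[int, ...] = (500, 250, 150, 50)
    dropout: float = 0.4
    dropout_after: tuple[int, ...] = (0, 1, 3)  # hidden layers 1, 2 and 4
    l1: float = 1e-5
    l2: float = 1e-4
    regularized_layer: int = 2  # hidden layer 3
    n_classes: int = 2


@dataclass
class CNNSpec:
    """Topology of the convolutional branch."""

    image_size: int = 64
    n_images: int = 1
    conv_filters: tuple[int, int] = (16, 32)
    kernel: int = 5
    pool: int = 2
    dropout: float = 0.8
    dense: tuple[int, int] = (64, 16)
    n_classes: int = 2

    @property
    def flatten_width(self) -> int:
        size = self.image_size
        for _ in self.conv_filters:
            size = (size - self.kernel + 1) // self.pool
        return size * size * self.conv_filters[-1]


@dataclass
class CombinedSpec:
    """Topology of the fused two-branch model."""

    mlp: MLPSpec = field(default_factory=MLPSpec)
    cnn: CNNSpec = field(default_factory=CNNSpec)
    fusion_dense: int = 128
    fusion: str = "softmax"  # or "penultimate"
    n_classes: int = 2


@dataclass
class TrainingConfig:
    """Optimizer and protocol settings for one training run."""

    learning_rate: float = 1e-4
    decay: float = 1e-4 / 200
    batch_size: int = 32
    max_epochs: int = 50
    patience: int = 2
    train_fraction: float = 0.8
    val_fraction: float = 0.1  # of the training split, stratified
    seed: int = 0
    restore_best: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1 or not 0 < self.val_fraction < 1:
            raise ValueError("fractions must lie in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be at least 1")


def build_mlp(spec: MLPSpec, rng: np.random.Generator, head: bool = True) -> nn.Sequential:
    layers: list[nn.Layer] = []
    n_in = spec.n_features
    for i, width in enumerate(spec.hidden):
        reg = dict(l1=spec.l1, l2=spec.l2) if i == spec.regularized_layer else {}
        layers += [nn.Dense(n_in, width, rng, **reg), nn.ReLU()]
        if i in spec.dropout_after:
            layers.append(nn.Dropout(spec.dropout))
        n_in = width
    if head:
        layers += [nn.Dense(n_in, spec.n_classes, rng), nn.Softmax()]
    return nn.Sequential(layers)


def build_cnn(spec: CNNSpec, rng: np.random.Generator, head: bool = True) -> nn.Sequential:
    f1, f2 = spec.conv_filters
    d1, d2 = spec.dense
    layers: list[nn.Layer] = [
        nn.Conv2D(spec.n_images, f1, spec.kernel, rng),
        nn.ReLU(),
        nn.BatchNorm(f1),
        nn.MaxPool2D(spec.pool),
        nn.Conv2D(f1, f2, spec.kernel, rng),
        nn.ReLU(),
        nn.BatchNorm(f2),
        nn.MaxPool2D(spec.pool),
        nn.Dropout(spec.dropout),
        nn.Flatten(),
        nn.Dense(spec.flatten_width, d1, rng),
        nn.ReLU(),
        nn.BatchNorm(d1),
        nn.Dropout(spec.dropout),
        nn.Dense(d1, d2, rng),
        nn.ReLU(),
    ]
    if head:
        layers += [nn.Dense(d2, spec.n_classes, rng), nn.Softmax()]
    return nn.Sequential(layers)


def build_combined(spec: CombinedSpec, rng: np.random.Generator) -> nn.TwoBranchNet:
    if spec.fusion not in ("softmax", "penultimate"):
        raise ValueError("fusion must be 'softmax' or 'penultimate'")
    with_head = spec.fusion == "softmax"
    mlp = build_mlp(spec.mlp, rng, head=with_head)
    cnn = build_cnn(spec.cnn, rng, head=with_head)
    fusion_in = (
        spec.mlp.n_classes + spec.cnn.n_classes
        if with_head
        else spec.mlp.hidden[-1] + spec.cnn.dense[-1]
    )
    head = nn.Sequential(
        [
            nn.Dense(fusion_in, spec.fusion_dense, rng),
            nn.ReLU(),
            nn.Dense(spec.fusion_dense, spec.n_classes, rng),
            nn.Softmax(),
        ]
    )
    return nn.TwoBranchNet(mlp, cnn, head)


def build(spec, seed: int = 0):
    """Build an untrained model from a spec, reproducibly under ``seed``."""
    rng = np.random.default_rng(seed)
    if isinstance(spec, MLPSpec):
        return build_mlp(spec, rng)
    if isinstance(spec, CNNSpec):
        return build_cnn(spec, rng)
    if isinstance(spec, CombinedSpec):
        return build_combined(spec, rng)
    raise TypeError(f"unknown spec type {type(spec).__name__}")


def _as_onehot(labels: np.ndarray, n_classes: int = 2) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def _check_inputs(model, x) -> None:
    if isinstance(model, nn.TwoBranchNet):
        if not (isinstance(x, (tuple, list)) and len(x) == 2):
            raise ValueError("a combined model needs a (features, images) input pair")
    elif isinstance(x, (tuple, list)):
        raise ValueError("a single-branch model takes a single input array")


def train(
    model,
    x,
    labels: np.ndarray,
    cfg: TrainingConfig | None = None,
) -> nn.TrainingHistory:
    """Train a built model in place; returns the loss/accuracy history.

    ``x`` is a feature table ``(n, 15)`` for the MLP, an image array
    ``(n, 64, 64, c)`` for the CNN, or a tuple of both for the combined
    model.  A stratified ``val_fraction`` of the rows is held out to drive
    early stopping.
    """
    cfg = cfg or TrainingConfig()
    _check_inputs(model, x)
    labels = np.asarray(labels, dtype=int)
    if len(labels) == 0:
        raise ValueError("empty training set")
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")

    idx_train, idx_val = train_test_split(
        np.arange(len(labels)),
        test_size=cfg.val_fraction,
        stratify=labels,
        random_state=cfg.seed % (2**32),
    )
    y = _as_onehot(labels)
    return nn.fit(
        model,
        nn._take(x, idx_train),
        y[idx_train],
        nn._take(x, idx_val),
        y[idx_val],
        max_epochs=cfg.max_epochs,
        batch_size=cfg.batch_size,
        optimizer=nn.Adam(lr=cfg.learning_rate, decay=cfg.decay),
        patience=cfg.patience,
        seed=cfg.seed,
        restore_best=cfg.restore_best,
    )


def predict_proba(model, x) -> np.ndarray:
    """Class-probability pairs (healthy, pathological) per segment."""
    _check_inputs(model, x)
    probs = model.predict(x)
    if probs.ndim != 2:
        raise ValueError("model output must be (n, 2)")
    return probs
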