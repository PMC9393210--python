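"""A compact, deterministic NumPy neural-network engine.

Implements exactly the ingredients the FHR classifier needs — dense,
convolutional (valid padding, im2col), max-pooling, batch-normalization,
dropout, flatten, softmax layers; categorical cross-entropy; the Adam
optimizer with a hyperbolic learning-rate decay; mini-batch training with
early stopping on validation loss.  Everything is seeded through
``numpy.random.Generator`` instances, so two runs with the same seed are
bit-identical on a single thread.

Array convention: channels-last.  Tabular inputs are ``(batch, features)``;
image inputs are ``(batch, height, width, channels)``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Layer",
    "Dense",
    "ReLU",
    "Softmax",
    "Dropout",
    "BatchNorm",
    "Conv2D",
    "MaxPool2D",
    "Flatten",
    "Sequential",
    "TwoBranchNet",
    "Adam",
    "TrainingHistory",
    "cross_entropy",
    "fit",
    "evaluate_loss",
]

_EPS = 1e-12

#: Engine dtype; single precision is ample for these nets and twice as fast.
DTYPE = np.float32


class Layer:
    """Base layer: forward/backward plus named parameters and gradients."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def penalty(self) -> float:
        return 0.0


class Dense(Layer):
    """Fully connected layer with optional L1/L2 kernel penalties."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, l1: float = 0.0, l2: float = 0.0):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)  # He initialization for rectifier nets
        self.params = {
            "W": rng.normal(0.0, scale, (n_in, n_out)).astype(DTYPE),
            "b": np.zeros(n_out, dtype=DTYPE),
        }
        self.l1, self.l2 = l1, l2

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        w = self.params["W"]
        self.grads = {"W": self._x.T @ grad, "b": grad.sum(axis=0)}
        if self.l1:
            self.grads["W"] = self.grads["W"] + self.l1 * np.sign(w)
        if self.l2:
            self.grads["W"] = self.grads["W"] + 2.0 * self.l2 * w
        return grad @ w.T

    def penalty(self):
        w = self.params["W"]
        return self.l1 * np.abs(w).sum() + self.l2 * (w**2).sum()


class ReLU(Layer):
    def forward(self, x, training, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Softmax(Layer):
    """Softmax over the last axis (the 2-way class output)."""

    def forward(self, x, training, rng):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        self._y = e / e.sum(axis=-1, keepdims=True)
        return self._y

    def backward(self, grad):
        y = self._y
        return y * (grad - (grad * y).sum(axis=-1, keepdims=True))


class Dropout(Layer):
    """Inverted dropout; ``p`` is the drop probability."""

    def __init__(self, p: float):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("drop probability must lie in [0, 1)")
        self.p = p

    def forward(self, x, training, rng):
        if not training or self.p == 0:
            self._mask = None
            return x
        self._mask = ((rng.random(x.shape) >= self.p) / (1.0 - self.p)).astype(x.dtype)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class BatchNorm(Layer):
    """Batch normalization over all axes but the last (feature/channel)."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params = {"gamma": np.ones(n_features, dtype=DTYPE), "beta": np.zeros(n_features, dtype=DTYPE)}
        self.running_mean = np.zeros(n_features, dtype=DTYPE)
        self.running_var = np.ones(n_features, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, training, rng):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._axes = axes
        self._n = x.size // x.shape[-1]
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, grad):
        axes, n = self._axes, self._n
        self.grads = {
            "gamma": (grad * self._xhat).sum(axis=axes),
            "beta": grad.sum(axis=axes),
        }
        g = grad * self.params["gamma"]
        return (
            g - g.mean(axis=axes) - self._xhat * (g * self._xhat).mean(axis=axes)
        ) / self._std


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B,H,W,C) -> (B, OH, OW, k*k*C) valid-padding patch matrix."""
    view = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    # view: (B, OH, OW, C, k, k) -> (B, OH, OW, k, k, C)
    view = view.transpose(0, 1, 2, 4, 5, 3)
    b, oh, ow = view.shape[:3]
    return view.reshape(b, oh, ow, -1)


class Conv2D(Layer):
    """Valid-padding 2-D convolution (channels-last), via im2col."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int, rng: np.random.Generator):
        super().__init__()
        fan_in = ksize * ksize * in_ch
        scale = np.sqrt(2.0 / fan_in)
        self.params = {
            "W": rng.normal(0.0, scale, (fan_in, out_ch)).astype(DTYPE),
            "b": np.zeros(out_ch, dtype=DTYPE),
        }
        self.k, self.in_ch, self.out_ch = ksize, in_ch, out_ch

    def forward(self, x, training, rng):
        self._xshape = x.shape
        self._col = _im2col(x, self.k)  # (B, OH, OW, k*k*C)
        return self._col @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        b, oh, ow, _ = grad.shape
        col2 = self._col.reshape(-1, self._col.shape[-1])
        g2 = grad.reshape(-1, self.out_ch)
        self.grads = {"W": col2.T @ g2, "b": g2.sum(axis=0)}

        # scatter the patch gradients back onto the input grid
        dcol = (g2 @ self.params["W"].T).reshape(b, oh, ow, self.k, self.k, self.in_ch)
        dx = np.zeros(self._xshape, dtype=grad.dtype)
        for di in range(self.k):
            for dj in range(self.k):
                dx[:, di : di + oh, dj : dj + ow, :] += dcol[:, :, :, di, dj, :]
        return dx


class MaxPool2D(Layer):
    """Non-overlapping max pooling with a square pool (default 2 x 2)."""

    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x, training, rng):
        p = self.pool
        b, h, w, c = x.shape
        oh, ow = h // p, w // p
        self._in_shape = x.shape
        r = x[:, : oh * p, : ow * p, :].reshape(b, oh, p, ow, p, c)
        r = r.transpose(0, 1, 3, 5, 2, 4).reshape(b, oh, ow, c, p * p)
        self._arg = r.argmax(axis=-1)
        return np.take_along_axis(r, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        p = self.pool
        b, h, w, c = self._in_shape
        oh, ow = h // p, w // p
        dr = np.zeros((b, oh, ow, c, p * p), dtype=grad.dtype)
        np.put_along_axis(dr, self._arg[..., None], grad[..., None], axis=-1)
        dr = dr.reshape(b, oh, ow, c, p, p).transpose(0, 1, 4, 2, 5, 3)
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        dx[:, : oh * p, : ow * p, :] = dr.reshape(b, oh * p, ow * p, c)
        return dx


class Flatten(Layer):
    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Sequential:
    """A plain layer chain with shared forward/backward plumbing."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, training: bool, rng: np.random.Generator) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        for i, layer in enumerate(self.layers):
            if layer.params:
                yield str(i), layer

    def penalty(self) -> float:
        return sum(layer.penalty() for layer in self.layers)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, training=False, rng=np.random.default_rng(0))


class TwoBranchNet:
    """Two parallel branches whose outputs are concatenated into a head.

    ``forward`` takes a pair ``(x_a, x_b)``; each branch runs on its own
    input, the outputs are concatenated on the feature axis and passed
    through the fusion head.
    """

    def __init__(self, branch_a: Sequential, branch_b: Sequential, head: Sequential):
        self.branch_a, self.branch_b, self.head = branch_a, branch_b, head

    def forward(self, x, training: bool, rng: np.random.Generator) -> np.ndarray:
        xa, xb = x
        ya = self.branch_a.forward(xa, training, rng)
        yb = self.branch_b.forward(xb, training, rng)
        self._split = ya.shape[-1]
        return self.head.forward(np.concatenate([ya, yb], axis=-1), training, rng)

    def backward(self, grad: np.ndarray) -> None:
        g = self.head.backward(grad)
        self.branch_a.backward(g[:, : self._split])
        self.branch_b.backward(g[:, self._split :])

    def parameters(self):
        for tag, net in (("a", self.branch_a), ("b", self.branch_b), ("h", self.head)):
            for name, layer in net.parameters():
                yield f"{tag}.{name}", layer

    def penalty(self) -> float:
        return self.branch_a.penalty() + self.branch_b.penalty() + self.head.penalty()

    def predict(self, x) -> np.ndarray:
        return self.forward(x, training=False, rng=np.random.default_rng(0))


def cross_entropy(probs: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy on probabilities, with its gradient."""
    p = np.clip(probs, _EPS, 1.0)
    onehot = np.asarray(onehot, dtype=p.dtype)
    loss = float(-(onehot * np.log(p)).sum() / len(p))
    grad = -(onehot / p) / len(p)
    return loss, grad


class Adam:
    """Adam with the hyperbolic decay schedule lr_t = lr0 / (1 + decay * t)."""

    def __init__(self, lr: float = 1e-4, decay: float = 1e-4 / 200, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.lr0, self.decay = lr, decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def lr_at(self, epoch: int) -> float:
        return self.lr0 / (1.0 + self.decay * epoch)

    def step(self, model, epoch: int) -> None:
        self.t += 1
        lr = self.lr_at(epoch)
        for key, layer in model.parameters():
            for name, value in layer.params.items():
                if name not in layer.grads:
                    continue
                pkey = f"{key}:{name}"
                g = layer.grads[name]
                m = self.m.setdefault(pkey, np.zeros_like(value))
                v = self.v.setdefault(pkey, np.zeros_like(value))
                m[...] = self.beta1 * m + (1 - self.beta1) * g
                v[...] = self.beta2 * v + (1 - self.beta2) * g**2
                mhat = m / (1 - self.beta1**self.t)
                vhat = v / (1 - self.beta2**self.t)
                value -= lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainingHistory:
    """Per-epoch loss/accuracy curves for train and validation sets."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    stopped_epoch: int | None = None

    @property
    def epochs_run(self) -> int:
        return len(self.train_loss)


def _batch_slices(n: int, batch_size: int, order: np.ndarray):
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def _take(x, idx):
    if isinstance(x, (tuple, list)):
        return tuple(xi[idx] for xi in x)
    return x[idx]


def evaluate_loss(model, x, onehot, batch_size: int = 256) -> tuple[float, float]:
    """Mean cross-entropy and accuracy in evaluation mode."""
    n = len(onehot)
    rng = np.random.default_rng(0)
    losses, correct = 0.0, 0
    for idx in _batch_slices(n, batch_size, np.arange(n)):
        p = model.forward(_take(x, idx), training=False, rng=rng)
        loss, _ = cross_entropy(p, onehot[idx])
        losses += loss * len(idx)
        correct += int((p.argmax(axis=1) == onehot[idx].argmax(axis=1)).sum())
    return losses / n, correct / n


def _snapshot(model):
    return copy.deepcopy([layer.params for _, layer in _unique_layers(model)]), copy.deepcopy(
        [(layer.running_mean.copy(), layer.running_var.copy())
         for _, layer in _unique_layers(model) if isinstance(layer, BatchNorm)]
    )


def _unique_layers(model):
    seen = set()
    for name, layer in model.parameters():
        if id(layer) not in seen:
            seen.add(id(layer))
            yield name, layer


def _restore(model, snap) -> None:
    params, bn_stats = snap
    bn_iter = iter(bn_stats)
    for saved, (_, layer) in zip(params, _unique_layers(model)):
        for k in layer.params:
            layer.params[k][...] = saved[k]
        if isinstance(layer, BatchNorm):
            mean, var = next(bn_iter)
            layer.running_mean[...] = mean
            layer.running_var[...] = var


def fit(
    model,
    x_train,
    y_train: np.ndarray,
    x_val=None,
    y_val: np.ndarray | None = None,
    max_epochs: int = 50,
    batch_size: int = 32,
    optimizer: Adam | None = None,
    patience: int = 2,
    seed: int = 0,
    restore_best: bool = True,
) -> TrainingHistory:
    """Mini-batch training with early stopping on validation loss.

    ``y`` arrays are one-hot ``(n, 2)``.  Training halts once the
    validation loss has failed to improve for ``patience`` consecutive
    epochs (or after ``max_epochs``); with ``restore_best`` the weights of
    the best validation epoch are reinstated.  Without a validation set the
    loop simply runs ``max_epochs`` epochs.
    """
    n = len(y_train)
    if n == 0:
        raise ValueError("empty training set")
    if y_train.ndim != 2 or y_train.shape[1] != 2:
        raise ValueError("labels must be one-hot of shape (n, 2)")
    if len(np.unique(y_train.argmax(axis=1))) < 2:
        raise ValueError("training set must contain both classes")
    optimizer = optimizer or Adam()
    rng = np.random.default_rng(seed)
    history = TrainingHistory()

    best_loss, best_snap, stale = np.inf, None, 0
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        for idx in _batch_slices(n, batch_size, order):
            probs = model.forward(_take(x_train, idx), training=True, rng=rng)
            _, grad = cross_entropy(probs, y_train[idx])
            model.backward(grad)
            optimizer.step(model, epoch)

        tr_loss, tr_acc = evaluate_loss(model, x_train, y_train)
        history.train_loss.append(tr_loss + model.penalty())
        history.train_acc.append(tr_acc)

        if x_val is not None and y_val is not None and len(y_val):
            va_loss, va_acc = evaluate_loss(model, x_val, y_val)
            history.val_loss.append(va_loss)
            history.val_acc.append(va_acc)
            if va_loss < best_loss - 1e-12:
                best_loss, stale = va_loss, 0
                if restore_best:
                    best_snap = _snapshot(model)
            else:
                stale += 1
                if stale >= patience:
                    history.stopped_epoch = epoch
                    break

    if restore_best and best_snap is not None:
        _restore(model, best_snap)
    return history
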