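"""A compact convolutional network for multichannel count grids, in pure numpy.

Architecture (configurable): two blocks of 3x3 same-padded convolution + ReLU
+ 2x2 max-pool, a dense ReLU layer, and a 2-way softmax head.  Trained with
Adam on cross-entropy, mini-batches, and early stopping on validation loss.
The dataset at hand is small (hundreds of 5x16x16 tensors), so CPU numpy is
entirely adequate and the run is bit-reproducible from the seed: all
initialization and shuffling come from one ``numpy.random.Generator`` and the
forward/backward passes are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CNNSpec:
    """Architecture and training hyper-parameters."""

    conv_channels: tuple[int, int] = (8, 16)
    dense_units: int = 32
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    patience: int = 10      # early stopping on validation loss
    seed: int = 0


def _conv_windows(x: np.ndarray, k: int = 3) -> np.ndarray:
    """(B, C, H, W) -> sliding 3x3 windows (B, C, H, W, k, k), same padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    return np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))


class _Conv3x3:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))  # He initialization
        self.W = rng.normal(0.0, scale, size=(c_out, c_in, 3, 3))
        self.b = np.zeros(c_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._win = _conv_windows(x)
        return np.einsum("bchwij,ocij->bohw", self._win, self.W) + self.b[:, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = np.einsum("bchwij,bohw->ocij", self._win, dout)
        self.db = dout.sum(axis=(0, 2, 3))
        # gradient w.r.t. input = "full" correlation with the flipped kernel
        dwin = _conv_windows(dout)
        return np.einsum("bohwij,ocij->bchw", dwin, self.W[:, :, ::-1, ::-1])

    def params(self):
        return [("W", self), ("b", self)]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class _MaxPool2:
    def forward(self, x):
        b, c, h, w = x.shape
        xr = (
            x.reshape(b, c, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(b, c, h // 2, w // 2, 4)
        )
        self._argmax = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        b, c, h, w = self._in_shape
        dxr = np.zeros((b, c, h // 2, w // 2, 4))
        np.put_along_axis(dxr, self._argmax[..., None], dout[..., None], axis=-1)
        return (
            dxr.reshape(b, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(b, c, h, w)
        )


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)


class GridCNN:
    """The grid-image classifier; use :func:`train_cnn` to fit one."""

    def __init__(self, input_shape: tuple[int, int, int], spec: CNNSpec):
        c, h, w = input_shape
        if h % 4 or w % 4:
            raise ValueError("grid height and width must be multiples of 4")
        rng = np.random.default_rng(spec.seed)
        c1, c2 = spec.conv_channels
        self.spec = spec
        self.input_shape = input_shape
        self.conv1, self.relu1, self.pool1 = _Conv3x3(c, c1, rng), _ReLU(), _MaxPool2()
        self.conv2, self.relu2, self.pool2 = _Conv3x3(c1, c2, rng), _ReLU(), _MaxPool2()
        self._flat = c2 * (h // 4) * (w // 4)
        self.fc1, self.relu3 = _Dense(self._flat, spec.dense_units, rng), _ReLU()
        self.fc2 = _Dense(spec.dense_units, 2, rng)
        self.history = TrainingHistory()
        self._rng = rng
        self._adam_state: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._adam_t = 0

    # -- forward / backward -------------------------------------------------
    def _forward(self, x: np.ndarray) -> np.ndarray:
        h = self.pool1.forward(self.relu1.forward(self.conv1.forward(x)))
        h = self.pool2.forward(self.relu2.forward(self.conv2.forward(h)))
        h = h.reshape(len(x), -1)
        h = self.relu3.forward(self.fc1.forward(h))
        return self.fc2.forward(h)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities, shape (B, 2); rows sum to 1."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:
            x = x[None]
        logits = self._forward(x)
        logits = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)

    def _backward(self, dlogits: np.ndarray) -> None:
        d = self.fc2.backward(dlogits)
        d = self.fc1.backward(self.relu3.backward(d))
        b = len(dlogits)
        c2 = self.spec.conv_channels[1]
        side = self.input_shape[1] // 4
        d = d.reshape(b, c2, side, side)
        d = self.conv2.backward(self.relu2.backward(self.pool2.backward(d)))
        self.conv1.backward(self.relu1.backward(self.pool1.backward(d)))

    # -- optimization -------------------------------------------------------
    def _adam_step(self) -> None:
        lr, b1, b2, eps = self.spec.learning_rate, 0.9, 0.999, 1e-8
        self._adam_t += 1
        t = self._adam_t
        for layer in (self.conv1, self.conv2, self.fc1, self.fc2):
            for name in ("W", "b"):
                g = getattr(layer, "d" + name)
                p = getattr(layer, name)
                key = id(layer) * 2 + (name == "b")
                m, v = self._adam_state.get(key, (np.zeros_like(p), np.zeros_like(p)))
                m = b1 * m + (1 - b1) * g
                v = b2 * v + (1 - b2) * g**2
                self._adam_state[key] = (m, v)
                mhat = m / (1 - b1**t)
                vhat = v / (1 - b2**t)
                setattr(layer, name, p - lr * mhat / (np.sqrt(vhat) + eps))

    def _loss_acc(self, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        p = self.predict_proba(x)
        loss = -np.mean(np.log(p[np.arange(len(y)), y] + 1e-12))
        acc = float(np.mean(p.argmax(axis=1) == y))
        return float(loss), acc

    def _snapshot(self):
        return [
            (layer, name, getattr(layer, name).copy())
            for layer in (self.conv1, self.conv2, self.fc1, self.fc2)
            for name in ("W", "b")
        ]

    @staticmethod
    def _restore(snapshot):
        for layer, name, value in snapshot:
            setattr(layer, name, value)


def train_cnn(
    tensors: np.ndarray,
    labels: np.ndarray,
    spec: CNNSpec | None = None,
    val_tensors: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
) -> GridCNN:
    """Train a :class:`GridCNN` on (B, C, m, n) tensors and 0/1 labels.

    With a validation set, early-stops on validation loss (``spec.patience``)
    and restores the best weights; the loss/accuracy trajectory is kept in
    ``model.history``.  A single-class training set is an error.
    """
    spec = spec or CNNSpec()
    x = np.asarray(tensors, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    model = GridCNN(x.shape[1:], spec)
    rng = model._rng
    has_val = val_tensors is not None and len(val_tensors) > 0
    best_val = np.inf
    best_weights = None
    stale = 0
    for _ in range(spec.epochs):
        order = rng.permutation(len(x))
        for start in range(0, len(x), spec.batch_size):
            idx = order[start : start + spec.batch_size]
            xb, yb = x[idx], y[idx]
            p = model.predict_proba(xb)
            dlogits = p.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            model._backward(dlogits)
            model._adam_step()
        tr_loss, tr_acc = model._loss_acc(x, y)
        model.history.train_loss.append(tr_loss)
        model.history.train_acc.append(tr_acc)
        if has_val:
            vl, va = model._loss_acc(np.asarray(val_tensors, float), np.asarray(val_labels, int))
            model.history.val_loss.append(vl)
            model.history.val_acc.append(va)
            if vl < best_val - 1e-6:
                best_val, best_weights, stale = vl, model._snapshot(), 0
            else:
                stale += 1
                if stale >= spec.patience:
                    break
    if best_weights is not None:
        GridCNN._restore(best_weights)
    return model


def predict_cnn(model: GridCNN, tensor: np.ndarray) -> float:
    """Probability of the heart-failure class for one (C, m, n) tensor."""
    return float(model.predict_proba(tensor)[0, 1])
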