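"""Convolutional network feature extraction.

An AlexNet-style network classifies each 227×227×3 window as polyp or
nonpolyp; the post-ReLU activations of its second fully connected layer
(4096 units) are exposed as a learned feature vector.  The network is
implemented directly in NumPy (im2col convolutions, hand-derived backward
passes) and trained with minibatch SGD with momentum on the cross-entropy
loss.  All randomness — weight initialization and minibatch shuffling —
derives from one integer seed, so training is bit-reproducible.

Architecture (fixed):
    conv(96, 11×11, stride 4, pad 0) → relu → maxpool(3×3, stride 2)
    conv(256, 5×5, stride 1, pad 2)  → relu → maxpool(3×3, stride 2)
    conv(384, 3×3, stride 1, pad 1)  → relu
    conv(384, 3×3, stride 1, pad 1)  → relu
    conv(256, 3×3, stride 1, pad 1)  → relu → maxpool(3×3, stride 2)
    dense(4096) → relu → dense(4096) → relu → dense(n_classes) → softmax
"""

from __future__ import annotations

import json

import numpy as np
from numpy.lib.stride_tricks import as_strided
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import DegenerateLabelsError, ShapeError
from .frames import WINDOW_SIZE, Window

N_CNN_FEATURES = 4096

__all__ = [
    "relu",
    "softmax",
    "PolypNet",
    "CnnFeatureExtractor",
    "N_CNN_FEATURES",
]


def relu(x):
    """Rectified linear unit, f(x) = max(0, x)."""
    return np.maximum(0, x)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last axis."""
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# im2col / col2im


def _out_size(n: int, k: int, stride: int, pad: int) -> int:
    return (n + 2 * pad - k) // stride + 1


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = _out_size(h, kh, stride, pad)
    ow = _out_size(w, kw, stride, pad)
    sn, sc, sh, sw = x.strides
    view = as_strided(
        x,
        shape=(n, c, oh, ow, kh, kw),
        strides=(sn, sc, sh * stride, sw * stride, sh, sw),
        writeable=False,
    )
    cols = np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5)).reshape(n * oh * ow, c * kh * kw)
    return cols, oh, ow


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w = x_shape
    oh = _out_size(h, kh, stride, pad)
    ow = _out_size(w, kw, stride, pad)
    dx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols6 = cols.reshape(n, oh, ow, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cols6[:, :, i, j]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


# ---------------------------------------------------------------------------
# Layers


class _Conv:
    def __init__(self, c_in, c_out, kernel, stride, pad, rng, is_first=False):
        fan_in = c_in * kernel * kernel
        self.w = (rng.standard_normal((c_out, c_in, kernel, kernel)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.is_first = is_first  # the input image needs no gradient

    def forward(self, x, train=False):
        cols, oh, ow = _im2col(x, self.kernel, self.kernel, self.stride, self.pad)
        out = cols @ self.w.reshape(self.w.shape[0], -1).T + self.b
        if train:
            self._cache = (x.shape, cols)
        n = x.shape[0]
        return out.reshape(n, oh, ow, -1).transpose(0, 3, 1, 2)

    def backward(self, dout):
        x_shape, cols = self._cache
        self._cache = None
        c_out = dout.shape[1]
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, c_out)
        self.dw = (dflat.T @ cols).reshape(self.w.shape)
        self.db = dflat.sum(axis=0)
        if self.is_first:
            return None
        dcols = dflat @ self.w.reshape(c_out, -1)
        return _col2im(dcols, x_shape, self.kernel, self.kernel, self.stride, self.pad)

    def out_shape(self, shape):
        c, h, w = shape
        return (self.w.shape[0], _out_size(h, self.kernel, self.stride, self.pad), _out_size(w, self.kernel, self.stride, self.pad))


class _ReLU:
    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(0, x)

    def backward(self, dout):
        return dout * self._mask

    def out_shape(self, shape):
        return shape


class _MaxPool:
    def __init__(self, kernel=3, stride=2):
        self.kernel, self.stride = kernel, stride

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        k, s = self.kernel, self.stride
        oh, ow = _out_size(h, k, s, 0), _out_size(w, k, s, 0)
        sn, sc, sh, sw = x.strides
        view = as_strided(x, shape=(n, c, oh, ow, k, k), strides=(sn, sc, sh * s, sw * s, sh, sw), writeable=False)
        flat = view.reshape(n, c, oh, ow, k * k)
        if train:
            amax = flat.argmax(axis=-1)
            self._cache = (x.shape, amax)
        return flat.max(axis=-1)

    def backward(self, dout):
        x_shape, amax = self._cache
        self._cache = None
        n, c, h, w = x_shape
        k, s = self.kernel, self.stride
        oh, ow = dout.shape[2], dout.shape[3]
        ni, ci, yi, xi = np.meshgrid(np.arange(n), np.arange(c), np.arange(oh), np.arange(ow), indexing="ij")
        rows = yi * s + amax // k
        cols = xi * s + amax % k
        dx = np.zeros(x_shape, dtype=dout.dtype)
        # overlapping pools: gradients accumulate
        np.add.at(dx, (ni, ci, rows, cols), dout)
        return dx

    def out_shape(self, shape):
        c, h, w = shape
        return (c, _out_size(h, self.kernel, self.stride, 0), _out_size(w, self.kernel, self.stride, 0))


class _Flatten:
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)

    def out_shape(self, shape):
        return (int(np.prod(shape)),)


class _Dense:
    def __init__(self, n_in, n_out, rng):
        self.w = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        self._x = None
        return dout @ self.w.T

    def out_shape(self, shape):
        return (self.w.shape[1],)


class PolypNet:
    """The fixed AlexNet-style architecture with seeded initialization."""

    INPUT_SHAPE = (3, WINDOW_SIZE, WINDOW_SIZE)

    def __init__(self, n_classes: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.n_classes = n_classes
        self.seed = seed
        self.layers = [
            _Conv(3, 96, 11, 4, 0, rng, is_first=True), _ReLU(), _MaxPool(3, 2),
            _Conv(96, 256, 5, 1, 2, rng), _ReLU(), _MaxPool(3, 2),
            _Conv(256, 384, 3, 1, 1, rng), _ReLU(),
            _Conv(384, 384, 3, 1, 1, rng), _ReLU(),
            _Conv(384, 256, 3, 1, 1, rng), _ReLU(), _MaxPool(3, 2),
            _Flatten(),
            _Dense(9216, 4096, rng), _ReLU(),
            _Dense(4096, 4096, rng), _ReLU(),  # fc2: the feature layer
            _Dense(4096, n_classes, rng),
        ]
        self._fc2_relu_index = 17  # output of this layer is the 4096-D feature vector

    # -- shape arithmetic ---------------------------------------------------
    def shape_chain(self) -> list[tuple]:
        """Output shape of every layer for a single 227×227×3 input."""
        shapes = []
        shape = self.INPUT_SHAPE
        for layer in self.layers:
            shape = layer.out_shape(shape)
            shapes.append(shape)
        return shapes

    # -- passes -------------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch in NCHW float32 layout."""
        if x.shape[1:] != self.INPUT_SHAPE:
            raise ShapeError(f"expected input of shape (n,) + {self.INPUT_SHAPE}, got {x.shape}")
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def features(self, x: np.ndarray) -> np.ndarray:
        """Post-ReLU activations of fully connected layer 2 (n, 4096)."""
        if x.shape[1:] != self.INPUT_SHAPE:
            raise ShapeError(f"expected input of shape (n,) + {self.INPUT_SHAPE}, got {x.shape}")
        for layer in self.layers[: self._fc2_relu_index + 1]:
            x = layer.forward(x, train=False)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x))

    # -- training -----------------------------------------------------------
    def _trainable(self):
        return [l for l in self.layers if isinstance(l, (_Conv, _Dense))]

    def train_step(self, x, y_onehot, lr, momentum, velocities):
        logits = self.forward(x, train=True)
        p = softmax(logits)
        n = x.shape[0]
        eps = 1e-12
        loss = float(-np.sum(y_onehot * np.log(p + eps)) / n)
        dout = ((p - y_onehot) / n).astype(np.float32)
        for layer in reversed(self.layers):
            dout = layer.backward(dout) if hasattr(layer, "backward") else dout
        for layer, vel in zip(self._trainable(), velocities):
            vel["w"] = momentum * vel["w"] - lr * layer.dw
            vel["b"] = momentum * vel["b"] - lr * layer.db
            layer.w += vel["w"]
            layer.b += vel["b"]
        return loss

    def fit(self, x, y, epochs=10, lr=1e-3, momentum=0.9, batch_size=16, rng=None):
        """Minibatch SGD on cross-entropy; returns per-epoch mean losses."""
        rng = rng or np.random.default_rng(self.seed)
        n = x.shape[0]
        onehot = np.zeros((n, self.n_classes), dtype=np.float32)
        onehot[np.arange(n), y] = 1.0
        velocities = [
            {"w": np.zeros_like(l.w), "b": np.zeros_like(l.b)} for l in self._trainable()
        ]
        history = []
        for _ in range(epochs):
            order = rng.permutation(n)
            losses, weights = [], []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                losses.append(self.train_step(x[idx], onehot[idx], lr, momentum, velocities))
                weights.append(len(idx))
            history.append(float(np.average(losses, weights=weights)))
        return history

    # -- persistence ----------------------------------------------------------
    def state_dict(self) -> dict:
        state = {}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, (_Conv, _Dense)):
                state[f"w{i}"] = layer.w
                state[f"b{i}"] = layer.b
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self.layers):
            if isinstance(layer, (_Conv, _Dense)):
                w, b = np.asarray(state[f"w{i}"]), np.asarray(state[f"b{i}"])
                if w.shape != layer.w.shape or b.shape != layer.b.shape:
                    raise ShapeError(f"checkpoint tensor {i} has shape {w.shape}, expected {layer.w.shape}")
                layer.w = w.astype(np.float32)
                layer.b = b.astype(np.float32)


def _to_nchw(X) -> np.ndarray:
    """Windows / (n, S, S, 3) uint8 arrays → float32 NCHW in [0, 1]."""
    if isinstance(X, np.ndarray) and X.ndim == 4:
        arr = X
    else:
        arr = np.stack([w.pixels if isinstance(w, Window) else np.asarray(w) for w in X])
    if arr.ndim != 4 or arr.shape[3] != 3:
        raise ShapeError(f"expected (n, S, S, 3) windows, got {arr.shape}")
    return (arr.astype(np.float32) / 255.0).transpose(0, 3, 1, 2)


class CnnFeatureExtractor(TransformerMixin, BaseEstimator):
    """Trains the polyp/nonpolyp CNN and exposes fc2 activations as features.

    Parameters
    ----------
    epochs : int, default 10
        SGD epochs over the training windows.
    lr : float, default 1e-3
        Learning rate.
    momentum : float, default 0.9
        Classical momentum coefficient.
    batch_size : int, default 16
        Minibatch size.
    random_state : int, default 0
        Seed controlling initialization and shuffling; fixing it makes
        training bit-reproducible.

    Attributes
    ----------
    net_ : PolypNet
        The trained network.
    channel_means_ : ndarray of shape (3,)
        Per-channel means of the training windows (on the [0, 1] scale),
        subtracted before every forward pass.
    loss_history_ : list of float
        Mean cross-entropy per epoch.
    classes_ : ndarray
        Sorted class labels.
    """

    def __init__(self, epochs: int = 10, lr: float = 1e-3, momentum: float = 0.9, batch_size: int = 16, random_state: int = 0):
        self.epochs = epochs
        self.lr = lr
        self.momentum = momentum
        self.batch_size = batch_size
        self.random_state = random_state

    def fit(self, X, y):
        x = _to_nchw(X)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise DegenerateLabelsError("training requires at least two classes")
        self.channel_means_ = x.mean(axis=(0, 2, 3))
        x = x - self.channel_means_[None, :, None, None]
        self.net_ = PolypNet(n_classes=len(self.classes_), seed=self.random_state)
        rng = np.random.default_rng(self.random_state)
        self.loss_history_ = self.net_.fit(
            x, y_idx, epochs=self.epochs, lr=self.lr, momentum=self.momentum, batch_size=self.batch_size, rng=rng
        )
        return self

    def _preprocess(self, X) -> np.ndarray:
        return _to_nchw(X) - self.channel_means_[None, :, None, None]

    def transform(self, X, batch_size: int = 32) -> np.ndarray:
        """fc2 feature matrix (n, 4096); nonnegative, deterministic."""
        check_is_fitted(self, "net_")
        x = self._preprocess(X)
        return np.vstack([self.net_.features(x[i : i + batch_size]) for i in range(0, len(x), batch_size)])

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        return self.net_.predict_proba(self._preprocess(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        """Single-file checkpoint: architecture metadata + weight tensors."""
        check_is_fitted(self, "net_")
        meta = {
            "params": self.get_params(),
            "classes": self.classes_.tolist(),
            "loss_history": self.loss_history_,
            "n_classes": int(len(self.classes_)),
        }
        np.savez_compressed(
            path,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            channel_means=self.channel_means_,
            **self.net_.state_dict(),
        )

    @classmethod
    def load(cls, path) -> "CnnFeatureExtractor":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            est = cls(**meta["params"])
            est.classes_ = np.asarray(meta["classes"])
            est.loss_history_ = meta["loss_history"]
            est.channel_means_ = data["channel_means"]
            est.net_ = PolypNet(n_classes=meta["n_classes"], seed=meta["params"]["random_state"])
            est.net_.load_state_dict({k: data[k] for k in data.files if k[0] in "wb" and k not in ("meta",)})
        return est
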