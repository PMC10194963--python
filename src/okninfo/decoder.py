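"""CNN decoder of perceptual state from single OKN epochs.

A small convolutional network classifies 1.25-s slow-phase-velocity epochs
(625 samples at 500 Hz) as preceding a switch to the integrated or the
differentiated percept.  The architecture, splits, and training regime are
fixed:

* conv 8 filters 1x25 (ReLU, stride 1) -> max-pool 1x5 stride 2 ->
  conv 16 filters 2x50 (ReLU) -> max-pool 1x5 stride 2 ->
  conv 32 filters 2x75 (ReLU) -> dense 2 (softmax);
* stratified 70/15/15 train/validation/test split;
* SGD with momentum 0.9, mini-batches of 128, 30 epochs, cross-entropy
  loss, training set reshuffled every epoch, validation accuracy recorded
  every 10 mini-batches.

The 2x50 / 2x75 kernels span (feature-map, time): after the first
convolution the 8 feature maps are stacked as a second spatial axis, the
second convolution is a single-channel 2-D convolution, and the third an
ordinary 16-channel 2-D convolution.  A plain 1-D variant (kernels 50 and
75 over time only) is available via ``conv1d=True``.

The estimator follows the scikit-learn API (``fit`` / ``predict`` /
``predict_proba`` / ``score``, ``get_params`` / ``set_params``) and is
fully deterministic given ``random_state``; forward and backward passes
are plain numpy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "DecoderSpec",
    "SplitSpec",
    "OKNConvNet",
    "stratified_split",
    "build_decoder",
    "train_decoder",
    "evaluate_decoder",
    "cross_classify",
    "layer_output_length",
]


def layer_output_length(length_in: int, kernel: int, stride: int = 1) -> int:
    """Valid-convolution/pooling output length: floor((L - k) / s) + 1."""
    return (length_in - kernel) // stride + 1


@dataclass
class DecoderSpec:
    """The reference architecture and training regime."""

    input_length: int = 625
    conv_filters: tuple = (8, 16, 32)
    conv_kernels: tuple = ((1, 25), (2, 50), (2, 75))
    pool_size: int = 5
    pool_stride: int = 2
    dense_units: int = 2
    learning_rate: float = 0.01
    momentum: float = 0.9
    batch_size: int = 128
    epochs: int = 30
    validate_every: int = 10
    conv1d: bool = False


@dataclass
class SplitSpec:
    """Stratified 70/15/15 split."""

    train_frac: float = 0.70
    val_frac: float = 0.15
    test_frac: float = 0.15
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if abs(self.train_frac + self.val_frac + self.test_frac - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def stratified_split(labels, spec: SplitSpec | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition epoch indices into disjoint, exhaustive train/val/test
    sets with class proportions preserved (to within rounding).

    Returns index arrays ``(train, val, test)``; reproducible by seed.
    """
    spec = spec or SplitSpec()
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 3:
        raise ValueError("every class needs at least 3 examples")
    idx = np.arange(y.size)
    strat = y if spec.stratified else None
    holdout = spec.val_frac + spec.test_frac
    train, rest = train_test_split(idx, test_size=holdout, random_state=spec.seed, stratify=strat)
    strat_rest = y[rest] if spec.stratified else None
    val, test = train_test_split(
        rest, test_size=spec.test_frac / holdout, random_state=spec.seed, stratify=strat_rest
    )
    return np.sort(train), np.sort(val), np.sort(test)


# ---------------------------------------------------------------------------
# numpy layers (float32, valid padding, stride-1 convolutions)
# ---------------------------------------------------------------------------


class _Conv2D:
    def __init__(self, c_in, c_out, kh, kw, rng):
        fan_in = c_in * kh * kw
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.c_in, self.kh, self.kw = c_in, kh, kw

    @property
    def params(self):
        return [self.W, self.b]

    def out_shape(self, shape):
        c, h, w = shape
        if c != self.c_in or h < self.kh or w < self.kw:
            raise ValueError("input smaller than the layer's receptive field")
        return (self.W.shape[0], h - self.kh + 1, w - self.kw + 1)

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        hp, wp = h - self.kh + 1, w - self.kw + 1
        cols = sliding_window_view(x, (self.kh, self.kw), axis=(2, 3))
        cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(n, hp, wp, -1)
        out = cols @ self.W.T + self.b
        if train:
            self.cache = (x.shape, cols)
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, dout):
        xshape, cols = self.cache
        n, c, h, w = xshape
        c_out = self.W.shape[0]
        hp, wp = h - self.kh + 1, w - self.kw + 1
        dflat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1))  # (N,H',W',c_out)
        self.dW = np.tensordot(dflat, cols, axes=([0, 1, 2], [0, 1, 2]))
        self.db = dflat.sum(axis=(0, 1, 2))
        # input gradient: one small GEMM per kernel offset instead of a
        # full column-gradient tensor (memory- and cache-friendlier)
        wr = self.W.reshape(c_out, c, self.kh, self.kw)
        dmat = np.ascontiguousarray(dout.reshape(n, c_out, hp * wp).transpose(1, 0, 2)).reshape(c_out, -1)
        dx = np.zeros(xshape, dtype=dout.dtype)
        for i in range(self.kh):
            for j in range(self.kw):
                contrib = (wr[:, :, i, j].T @ dmat).reshape(c, n, hp, wp)
                dx[:, :, i : i + hp, j : j + wp] += contrib.transpose(1, 0, 2, 3)
        self.cache = None
        return dx

    @property
    def grads(self):
        return [self.dW, self.db]


class _ReLU:
    params: list = []
    grads: list = []

    def out_shape(self, shape):
        return shape

    def forward(self, x, train=True):
        mask = x > 0
        if train:
            self.mask = mask
        return x * mask

    def backward(self, dout):
        out = dout * self.mask
        self.mask = None
        return out


class _MapsToHeight:
    """Stack feature maps as a second spatial axis: (N,C,H,W)->(N,1,C*H,W)."""

    params: list = []
    grads: list = []

    def out_shape(self, shape):
        c, h, w = shape
        return (1, c * h, w)

    def forward(self, x, train=True):
        self.shape = x.shape
        n, c, h, w = x.shape
        return x.reshape(n, 1, c * h, w)

    def backward(self, dout):
        return dout.reshape(self.shape)


class _MaxPoolW:
    """Max pooling of width ``k`` and stride ``s`` along the time axis."""

    params: list = []
    grads: list = []

    def __init__(self, k=5, s=2):
        self.k, self.s = k, s

    def out_shape(self, shape):
        c, h, w = shape
        if w < self.k:
            raise ValueError("input shorter than pooling window")
        return (c, h, (w - self.k) // self.s + 1)

    def forward(self, x, train=True):
        wins = sliding_window_view(x, self.k, axis=3)[:, :, :, :: self.s, :]
        arg = wins.argmax(axis=-1)
        out = np.take_along_axis(wins, arg[..., None], axis=-1)[..., 0]
        if train:
            self.cache = (x.shape, arg)
        return out

    def backward(self, dout):
        xshape, arg = self.cache
        dx = np.zeros(xshape, dtype=dout.dtype)
        n_i, c_i, h_i, w_i = np.indices(dout.shape, sparse=False)
        src = w_i * self.s + arg
        np.add.at(dx, (n_i, c_i, h_i, src), dout)
        self.cache = None
        return dx


class _Flatten:
    params: list = []
    grads: list = []

    def out_shape(self, shape):
        return (int(np.prod(shape)),)

    def forward(self, x, train=True):
        self.shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self.shape)


class _Dense:
    def __init__(self, d_in, d_out, rng):
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), (d_out, d_in)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)

    @property
    def params(self):
        return [self.W, self.b]

    def out_shape(self, shape):
        return (self.W.shape[0],)

    def forward(self, x, train=True):
        if train:
            self.cache = x
        return x @ self.W.T + self.b

    def backward(self, dout):
        self.dW = dout.T @ self.cache
        self.db = dout.sum(axis=0)
        out = dout @ self.W
        self.cache = None
        return out

    @property
    def grads(self):
        return [self.dW, self.db]


def _softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class OKNConvNet(ClassifierMixin, BaseEstimator):
    """Convolutional classifier of perceptual state from OKN epochs.

    Parameters mirror :class:`DecoderSpec`; all defaults reproduce the
    reference architecture and training regime.  Fitted attributes carry a
    trailing underscore: ``classes_``, ``layers_``, ``n_params_``,
    ``training_log_`` (a DataFrame of per-batch loss and periodic
    validation accuracy), ``input_scale_``, ``layer_shapes_``.
    """

    def __init__(
        self,
        input_length: int = 625,
        conv_filters: tuple = (8, 16, 32),
        conv_kernels: tuple = ((1, 25), (2, 50), (2, 75)),
        pool_size: int = 5,
        pool_stride: int = 2,
        learning_rate: float = 0.01,
        momentum: float = 0.9,
        batch_size: int = 128,
        n_epochs: int = 30,
        validate_every: int = 10,
        conv1d: bool = False,
        random_state: int | None = None,
    ):
        self.input_length = input_length
        self.conv_filters = conv_filters
        self.conv_kernels = conv_kernels
        self.pool_size = pool_size
        self.pool_stride = pool_stride
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.validate_every = validate_every
        self.conv1d = conv1d
        self.random_state = random_state

    # -- architecture -------------------------------------------------------

    def _build(self, rng):
        f1, f2, f3 = self.conv_filters
        (kh1, kw1), (kh2, kw2), (kh3, kw3) = self.conv_kernels
        pool = lambda: _MaxPoolW(self.pool_size, self.pool_stride)
        layers = [_Conv2D(1, f1, kh1, kw1, rng), _ReLU()]
        if self.conv1d:
            layers += [pool(), _Conv2D(f1, f2, 1, kw2, rng), _ReLU(), pool(),
                       _Conv2D(f2, f3, 1, kw3, rng), _ReLU()]
        else:
            layers += [_MapsToHeight(), pool(), _Conv2D(1, f2, kh2, kw2, rng), _ReLU(), pool(),
                       _Conv2D(f2, f3, kh3, kw3, rng), _ReLU()]
        layers.append(_Flatten())
        shape = (1, 1, self.input_length)
        shapes = [shape]
        for lay in layers:
            shape = lay.out_shape(shape)
            shapes.append(shape)
        layers.append(_Dense(shape[0], 2, rng))
        shapes.append((2,))
        return layers, shapes

    def _forward(self, x, train=True):
        a = x.reshape(x.shape[0], 1, 1, -1).astype(np.float32)
        for lay in self.layers_:
            a = lay.forward(a, train=train)
        return a

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y, validation=None):
        """Train with SGD-momentum on cross-entropy loss.

        ``validation`` is an optional ``(X_val, y_val)`` pair whose accuracy
        is logged every ``validate_every`` mini-batches.
        """
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] != self.input_length:
            raise ValueError(f"X must be (n_epochs, {self.input_length})")
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size != 2:
            raise ValueError("exactly 2 classes required")
        rng = np.random.default_rng(self.random_state)
        self.layers_, self.layer_shapes_ = self._build(rng)
        self.n_params_ = int(sum(p.size for lay in self.layers_ for p in lay.params))
        scale = float(X.std())
        self.input_scale_ = scale if scale > 0 else 1.0
        Xs = X / self.input_scale_

        velocities = [np.zeros_like(p) for lay in self.layers_ for p in lay.params]
        log = []
        n = Xs.shape[0]
        batch_counter = 0
        for epoch in range(self.n_epochs):
            perm = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                sel = perm[start : start + self.batch_size]
                xb, yb = Xs[sel], y_idx[sel]
                logits = self._forward(xb, train=True)
                probs = _softmax(logits)
                loss = float(-np.mean(np.log(probs[np.arange(len(yb)), yb] + 1e-12)))
                dlogits = (probs - np.eye(2, dtype=np.float32)[yb]) / len(yb)
                grad = dlogits.astype(np.float32)
                for lay in reversed(self.layers_):
                    grad = lay.backward(grad)
                k = 0
                for lay in self.layers_:
                    for p, g in zip(lay.params, lay.grads):
                        velocities[k] = self.momentum * velocities[k] - self.learning_rate * g
                        p += velocities[k]
                        k += 1
                batch_counter += 1
                entry = {"epoch": epoch, "batch": batch_counter, "loss": loss}
                if validation is not None and batch_counter % self.validate_every == 0:
                    xv, yv = validation
                    entry["val_accuracy"] = float(np.mean(self.predict(xv) == np.asarray(yv)))
                log.append(entry)
        self.training_log_ = pd.DataFrame(log)
        self.n_iter_ = batch_counter
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "layers_")
        X = np.asarray(X, dtype=np.float32) / self.input_scale_
        out = []
        for start in range(0, X.shape[0], 256):
            logits = self._forward(X[start : start + 256], train=False)
            out.append(_softmax(logits))
        return np.vstack(out) if out else np.empty((0, 2))

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------


def build_decoder(spec: DecoderSpec | None = None, random_state: int | None = None) -> OKNConvNet:
    """Instantiate an untrained decoder from a :class:`DecoderSpec`."""
    spec = spec or DecoderSpec()
    return OKNConvNet(
        input_length=spec.input_length,
        conv_filters=spec.conv_filters,
        conv_kernels=spec.conv_kernels,
        pool_size=spec.pool_size,
        pool_stride=spec.pool_stride,
        learning_rate=spec.learning_rate,
        momentum=spec.momentum,
        batch_size=spec.batch_size,
        n_epochs=spec.epochs,
        validate_every=spec.validate_every,
        conv1d=spec.conv1d,
        random_state=random_state,
    )


def train_decoder(decoder: OKNConvNet, train: tuple, val: tuple | None = None) -> OKNConvNet:
    """Fit ``decoder`` on ``train = (X, y)`` with optional validation."""
    return decoder.fit(train[0], train[1], validation=val)


def evaluate_decoder(decoder: OKNConvNet, X_test, y_test) -> tuple[float, dict]:
    """Held-out accuracy and per-class confusion counts."""
    y_test = np.asarray(y_test)
    if y_test.size == 0:
        raise ValueError("empty test set")
    pred = decoder.predict(X_test)
    acc = float(np.mean(pred == y_test))
    confusion = {
        (str(true), str(p)): int(np.sum((y_test == true) & (pred == p)))
        for true in decoder.classes_
        for p in decoder.classes_
    }
    return acc, confusion


def cross_classify(decoder: OKNConvNet, X_other, y_other) -> float:
    """Accuracy of a decoder trained on one label/locking source when
    applied to epochs locked or labeled by another source."""
    X_other = np.asarray(X_other)
    if X_other.ndim != 2 or X_other.shape[1] != decoder.input_length:
        raise ValueError("epoch shape mismatch between locking sources")
    acc, _ = evaluate_decoder(decoder, X_other, y_other)
    return acc
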