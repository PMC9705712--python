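"""Lightweight convolutional classifier for 128x128 grayscale seed images.

A small CNN implemented directly on numpy (im2col convolutions, batch
normalization, 2x2 max pooling, dense layers with dropout, a softmax
head, Adam with per-epoch learning-rate decay, and early stopping).

Default architecture: four conv(3x3) -> BN -> ReLU -> maxpool(2x2) stages
with 16/32/64/128 filters, flatten (8*8*128 = 8192), dense(8) + dropout,
dense(232) + dropout, dense(12) softmax.  Training defaults follow the
classic small-data recipe: Adam at 1e-4 with decay 1e-4, early stopping
on the monitored loss plateau, a global (non-stratified) 75/25 split of
original images, and optional deterministic 86x augmentation of the
training partition only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.metrics import confusion_matrix

from .harness import RepetitionResult

_F32 = np.float32


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class _Layer:
    params: list  # list of [value, grad] pairs

    def __init__(self):
        self.params = []

    def forward(self, x, train: bool):
        raise NotImplementedError

    def backward(self, dout):
        raise NotImplementedError


class Conv2D(_Layer):
    """3x3 same-padding convolution, NHWC layout."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng):
        super().__init__()
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        fan_in = k * k * in_ch
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(in_ch, k, k, out_ch))
        self.w = [w.astype(_F32), np.zeros((in_ch, k, k, out_ch), _F32)]
        self.b = [np.zeros(out_ch, _F32), np.zeros(out_ch, _F32)]
        self.params = [self.w, self.b]

    def forward(self, x, train):
        n, h, w, _ = x.shape
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        cols = sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
        # cols: (N, H, W, C, k, k) -> (N*H*W, C*k*k)
        self._cols = np.ascontiguousarray(cols).reshape(n * h * w, -1)
        self._shape = (n, h, w)
        wmat = self.w[0].reshape(-1, self.out_ch)
        out = self._cols @ wmat + self.b[0]
        return out.reshape(n, h, w, self.out_ch)

    def backward(self, dout):
        n, h, w = self._shape
        dmat = dout.reshape(n * h * w, self.out_ch)
        self.w[1] += (self._cols.T @ dmat).reshape(self.w[0].shape)
        self.b[1] += dmat.sum(axis=0)
        dcols = dmat @ self.w[0].reshape(-1, self.out_ch).T
        dcols = dcols.reshape(n, h, w, self.in_ch, self.k, self.k)
        pad = self.k // 2
        dxp = np.zeros((n, h + 2 * pad, w + 2 * pad, self.in_ch), _F32)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, :, i, j]
        self._cols = None
        return dxp[:, pad:pad + h, pad:pad + w, :]


class BatchNorm(_Layer):
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = [np.ones(ch, _F32), np.zeros(ch, _F32)]
        self.beta = [np.zeros(ch, _F32), np.zeros(ch, _F32)]
        self.params = [self.gamma, self.beta]
        self.running_mean = np.zeros(ch, _F32)
        self.running_var = np.ones(ch, _F32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(_F32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(_F32)
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = (1.0 / np.sqrt(var + self.eps)).astype(_F32)
        self._xhat = ((x - mean) * self._istd).astype(_F32)
        self._m = np.prod([x.shape[a] for a in axes])
        self._train = train
        return self.gamma[0] * self._xhat + self.beta[0]

    def backward(self, dout):
        axes = tuple(range(dout.ndim - 1))
        s_dy = dout.sum(axis=axes)
        s_dy_xhat = (dout * self._xhat).sum(axis=axes)
        self.gamma[1] += s_dy_xhat
        self.beta[1] += s_dy
        g_istd = (self.gamma[0] * self._istd).astype(_F32)
        if not self._train:
            return dout * g_istd
        m = self._m
        # dx = g_istd * (dout - s_dy/m - xhat * s_dy_xhat/m), built in-place
        dx = dout * g_istd
        dx -= self._xhat * (g_istd * s_dy_xhat / m)
        dx -= g_istd * s_dy / m
        self._xhat = None
        return dx.astype(_F32)


class ReLU(_Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class LeakyReLU(_Layer):
    """Used on the narrow dense stages, where plain ReLU units die.

    An 8-unit fully-connected bottleneck under Adam loses most of its
    units to the dead-ReLU regime within a few steps and the network
    stops training; a small negative slope keeps gradient flowing
    without changing the parameter count.
    """

    def __init__(self, alpha: float = 0.05):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x).astype(_F32)

    def backward(self, dout):
        return np.where(self._mask, dout, self.alpha * dout).astype(_F32)


class MaxPool2(_Layer):
    """2x2 max pooling with stride 2 (mask-based gradient routing)."""

    def forward(self, x, train):
        n, h, w, c = x.shape
        r = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = r.max(axis=(2, 4))
        # ties route gradient to every maximal cell; with float activations
        # exact ties are vanishingly rare
        self._mask = r == out[:, :, None, :, None, :]
        self._shape = (n, h, w, c)
        return out

    def backward(self, dout):
        n, h, w, c = self._shape
        grad = self._mask * dout[:, :, None, :, None, :]
        self._mask = None
        return grad.reshape(n, h, w, c)


class Flatten(_Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(_Layer):
    def __init__(self, d_in: int, d_out: int, rng):
        super().__init__()
        w = rng.normal(0.0, math.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.w = [w.astype(_F32), np.zeros((d_in, d_out), _F32)]
        self.b = [np.zeros(d_out, _F32), np.zeros(d_out, _F32)]
        self.params = [self.w, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.w[0] + self.b[0]

    def backward(self, dout):
        self.w[1] += self._x.T @ dout
        self.b[1] += dout.sum(axis=0)
        dx = dout @ self.w[0].T
        self._x = None
        return dx


class Dropout(_Layer):
    def __init__(self, rate: float):
        super().__init__()
        self.rate = rate
        self.rng = np.random.default_rng(0)

    def forward(self, x, train):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return (x * self._mask).astype(_F32)

    def backward(self, dout):
        if self._mask is None:
            return dout
        return (dout * self._mask).astype(_F32)


# ---------------------------------------------------------------------------
# Architecture and network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer recipe of the seed classifier."""

    conv_filters: tuple[int, ...] = (16, 32, 64, 128)
    conv_kernel: int = 3
    pool_kernel: int = 2
    dense_widths: tuple[int, int] = (8, 232)
    dropout_rates: tuple[float, float] = (0.25, 0.25)
    output_classes: int = 12
    input_size: int = 128

    def __post_init__(self):
        if self.input_size <= 0 or self.input_size % (
                self.pool_kernel ** len(self.conv_filters)):
            raise ValueError("input_size must be divisible by the pooling factor")
        if any(f <= 0 for f in self.conv_filters) or \
           any(d <= 0 for d in self.dense_widths) or self.output_classes <= 0:
            raise ValueError("all layer widths must be positive")

    @property
    def spatial_after_conv(self) -> int:
        return self.input_size // self.pool_kernel ** len(self.conv_filters)


class SeedCNN:
    """Feed-forward network assembled from an :class:`ArchitectureSpec`."""

    def __init__(self, spec: ArchitectureSpec, rng_seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(rng_seed)
        layers: list[_Layer] = []
        ch = 1
        for f in spec.conv_filters:
            layers += [Conv2D(ch, f, spec.conv_kernel, rng), BatchNorm(f),
                       ReLU(), MaxPool2()]
            ch = f
        layers.append(Flatten())
        d_in = spec.spatial_after_conv ** 2 * ch
        for width, rate in zip(spec.dense_widths, spec.dropout_rates):
            layers += [Dense(d_in, width, rng), LeakyReLU(), Dropout(rate)]
            d_in = width
        layers.append(Dense(d_in, spec.output_classes, rng))
        self.layers = layers

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    def seed_dropout(self, rng_seed: int) -> None:
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = np.random.default_rng(rng_seed)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=_F32)
        if out.ndim == 3:
            out = out[..., None]
        for layer in self.layers:
            out = layer.forward(out, train)
        return out  # logits

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits.astype(_F32)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def zero_grads(self) -> None:
        for p in self.params:
            p[1][...] = 0

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        x = np.asarray(x, dtype=_F32)
        outs = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i:i + batch_size], train=False)
            outs.append(_softmax(logits))
        return np.concatenate(outs, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        return np.argmax(self.predict_proba(x, batch_size), axis=1)


def build_network(spec: ArchitectureSpec, rng_seed: int = 0) -> SeedCNN:
    """Instantiate the network with He-initialized weights."""
    return SeedCNN(spec, rng_seed=rng_seed)


def count_parameters(network: SeedCNN) -> int:
    """Number of trainable parameters (conv/dense weights+biases, BN gamma/beta)."""
    return int(sum(p[0].size for p in network.params))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _loss_and_dlogits(logits: np.ndarray, y_onehot: np.ndarray,
                      loss: str) -> tuple[float, np.ndarray]:
    p = _softmax(logits.astype(np.float64))
    n, k = p.shape
    eps = 1e-12
    if loss == "categorical":
        value = float(-(y_onehot * np.log(p + eps)).sum() / n)
        dlogits = (p - y_onehot) / n
    elif loss == "binary":
        value = float(-(y_onehot * np.log(p + eps)
                        + (1 - y_onehot) * np.log(1 - p + eps)).mean())
        dp = (p - y_onehot) / ((p * (1 - p)) + eps) / (n * k)
        dlogits = p * (dp - (p * dp).sum(axis=1, keepdims=True))
    else:
        raise ValueError("loss must be 'categorical' or 'binary'")
    return value, dlogits.astype(_F32)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Optimization settings (Adam with per-epoch learning-rate decay)."""

    learning_rate: float = 1e-4
    decay: float = 1e-4
    loss: str = "categorical"  # or "binary"
    max_epochs: int = 4500
    patience: int = 50
    min_delta: float = 1e-4
    batch_size: int = 32
    rng_seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.max_epochs < 1:
            raise ValueError("learning_rate must be > 0 and max_epochs >= 1")


@dataclass
class TrainedClassifier:
    network: SeedCNN
    spec: ArchitectureSpec
    history: list
    stop_reason: str

    def predict(self, x):
        return self.network.predict(x)

    def predict_proba(self, x):
        return self.network.predict_proba(x)


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p[0]) for p in params]
        self.v = [np.zeros_like(p[0]) for p in params]
        self.t = 0

    def step(self, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p[1]
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p[0] -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(_F32)


def desk_train_config(max_epochs: int = 30, rng_seed: int = 0) -> TrainConfig:
    """Scaled-down training preset for single-core demonstration runs.

    The full-protocol recipe (lr 1e-4, up to 4500 epochs, 86x augmentation)
    is impractical for quick runs; this preset raises the learning rate
    to 1e-3 and caps the epochs so a few hundred original images train
    in minutes.
    """
    return TrainConfig(learning_rate=1e-3, decay=1e-4, max_epochs=max_epochs,
                       patience=max_epochs, batch_size=32, rng_seed=rng_seed)


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    out = np.zeros((len(labels), n_classes), _F32)
    out[np.arange(len(labels)), labels] = 1.0
    return out


def train(network: SeedCNN, x: np.ndarray, y_onehot: np.ndarray,
          config: TrainConfig, x_val: np.ndarray | None = None,
          y_val_onehot: np.ndarray | None = None) -> TrainedClassifier:
    """Optimize the network; halts at max_epochs or on a loss plateau.

    Early stopping monitors the validation loss when a validation set is
    given, else the training loss; ``patience`` epochs without an
    improvement of at least ``min_delta`` stop the run.
    """
    x = np.asarray(x, dtype=_F32)
    if x.ndim == 3:
        x = x[..., None]
    y_onehot = np.asarray(y_onehot, dtype=_F32)
    if y_onehot.shape[1] != network.spec.output_classes:
        raise ValueError("label width does not match the network output")
    rng = np.random.default_rng(config.rng_seed)
    network.seed_dropout(config.rng_seed + 1)
    opt = _Adam(network.params, config.learning_rate)
    history = []
    best = np.inf
    since_best = 0
    stop_reason = "max-epochs"
    for epoch in range(config.max_epochs):
        lr = config.learning_rate / (1.0 + config.decay * epoch)
        order = rng.permutation(len(x))
        epoch_loss = 0.0
        correct = 0
        for i in range(0, len(x), config.batch_size):
            idx = order[i:i + config.batch_size]
            logits = network.forward(x[idx], train=True)
            value, dlogits = _loss_and_dlogits(logits, y_onehot[idx], config.loss)
            network.zero_grads()
            network.backward(dlogits)
            opt.step(lr)
            epoch_loss += value * len(idx)
            correct += int((np.argmax(logits, axis=1)
                            == np.argmax(y_onehot[idx], axis=1)).sum())
        entry = {"epoch": epoch, "loss": epoch_loss / len(x),
                 "accuracy": correct / len(x), "lr": lr}
        if x_val is not None:
            val_logits = network.forward(np.asarray(x_val, _F32), train=False)
            entry["val_loss"], _ = _loss_and_dlogits(
                val_logits, np.asarray(y_val_onehot, _F32), config.loss)
        history.append(entry)
        monitored = entry.get("val_loss", entry["loss"])
        if monitored < best - config.min_delta:
            best = monitored
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                stop_reason = "early-stop"
                break
    return TrainedClassifier(network=network, spec=network.spec,
                             history=history, stop_reason=stop_reason)


# ---------------------------------------------------------------------------
# Split, evaluation, repetitions
# ---------------------------------------------------------------------------

@dataclass
class CnnSplit:
    """Global random 75/25 split of original images."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    rng_seed: int

    def __post_init__(self):
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise ValueError("train and test overlap")


def make_cnn_split(dataset, rng_seed: int = 0,
                   test_frac: float = 0.25) -> CnnSplit:
    """Global (not per-class) split; test count = ceil(test_frac * N)."""
    n = dataset if isinstance(dataset, int) else len(dataset)
    if n < 4:
        raise ValueError("dataset must contain at least 4 images")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(n)
    n_test = math.ceil(test_frac * n)
    return CnnSplit(train_idx=np.sort(perm[n_test:]),
                    test_idx=np.sort(perm[:n_test]), rng_seed=rng_seed)


def evaluate(model, x_test: np.ndarray, y_test: np.ndarray,
             n_classes: int | None = None) -> tuple[float, np.ndarray]:
    """Accuracy and confusion counts on original (un-augmented) images."""
    network = model.network if isinstance(model, TrainedClassifier) else model
    k = n_classes or network.spec.output_classes
    pred = network.predict(x_test)
    cm = confusion_matrix(np.asarray(y_test, dtype=int), pred,
                          labels=np.arange(k))
    return float(np.trace(cm) / cm.sum()), cm


def run_cnn_repetitions(images: np.ndarray, labels: np.ndarray, n_rep: int,
                        config: TrainConfig,
                        spec: ArchitectureSpec | None = None,
                        augment_plan=None,
                        dihedral: bool = False) -> list[RepetitionResult]:
    """Repeat split -> (optional augment) -> train -> evaluate.

    Seeds increment per repetition; augmentation, when requested, is
    applied to the training partition only (test images stay original).
    ``augment_plan`` runs the full 86-variant expansion (slow);
    ``dihedral`` adds only the exact quarter-turn rotations, the cheap
    desk-scale route to orientation robustness.
    """
    from .augment import augment_image, dihedral_rotations
    from .preprocess import StandardImage

    images = np.asarray(images, dtype=_F32)
    labels = np.asarray(labels, dtype=int)
    spec = spec or ArchitectureSpec(output_classes=int(labels.max()) + 1)
    results = []
    for r in range(n_rep):
        seed = config.rng_seed + r
        split = make_cnn_split(len(images), rng_seed=seed)
        x_train = images[split.train_idx]
        y_train = labels[split.train_idx]
        if dihedral:
            x_train, y_train = dihedral_rotations(x_train, y_train)
        if augment_plan is not None:
            variants, vlabels = [], []
            for xi, yi in zip(x_train, y_train):
                si = StandardImage(pixels=xi, partition="train")
                for v in augment_image(si, augment_plan):
                    variants.append(v.pixels)
                    vlabels.append(yi)
            x_train = np.stack(variants)
            y_train = np.asarray(vlabels)
        net = build_network(spec, rng_seed=seed)
        rep_config = TrainConfig(**{**config.__dict__, "rng_seed": seed})
        model = train(net, x_train, one_hot(y_train, spec.output_classes),
                      rep_config)
        acc, cm = evaluate(model, images[split.test_idx],
                           labels[split.test_idx], spec.output_classes)
        results.append(RepetitionResult(index=r, accuracy=acc, confusion=cm))
    return results
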