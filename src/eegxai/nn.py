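"""A small 1-D convolutional seizure classifier, implemented in numpy.

The network follows the patient-specific seizure-onset-detection pattern:
1-D convolutions over a channels x L raw-EEG window with ReLU activations,
a dense layer, dropout between the fully connected layers, and a 2-unit
softmax output.  Training uses Adam (alpha=0.001, beta1=0.9, beta2=0.999,
eps=1e-7) on the cross-entropy loss, 100 epochs and batch size 100 by
default.  The architecture is config-driven: filter counts, kernel sizes
and strides can be replaced wholesale, and an optional weight-shared
("siamese") twin branch over two channel groups is available.

Everything is seeded: parameter init, batch shuffling and dropout masks,
so a fixed seed gives bit-identical training runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ArchConfig", "TrainingConfig", "CNNClassifier", "build_reference_cnn"]


@dataclass
class ArchConfig:
    """Layer hyperparameters of the reference network."""

    conv_filters: tuple[int, ...] = (16, 32)
    kernel_size: int = 5
    stride: int = 2
    dense_units: int = 64
    dropout: float = 0.25
    siamese: bool = False  # weight-shared twin branches over two channel halves

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class TrainingConfig:
    """Adam + cross-entropy training configuration."""

    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-7
    epochs: int = 100
    batch_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.beta1, self.beta2, self.eps) <= 0:
            raise ValueError("optimizer hyperparameters must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], cfg: TrainingConfig):
        self.cfg = cfg
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        c = self.cfg
        self.t += 1
        for k, p in params.items():
            g = grads[k]
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g * g
            mhat = self.m[k] / (1 - c.beta1 ** self.t)
            vhat = self.v[k] / (1 - c.beta2 ** self.t)
            p -= c.learning_rate * mhat / (np.sqrt(vhat) + c.eps)


def _conv_forward(x, W, b, stride):
    # x: (N, Cin, L); W: (F, Cin*k); returns out (N, F, P) and the im2col cache
    k = W.shape[1] // x.shape[1]
    col = sliding_window_view(x, k, axis=2)[:, :, ::stride, :]  # (N, Cin, P, k)
    col = col.transpose(0, 2, 1, 3).reshape(x.shape[0], -1, W.shape[1])  # (N, P, Cin*k)
    out = np.einsum("npq,fq->nfp", col, W) + b[None, :, None]
    return out, col


def _conv_backward(dout, col, W, x_shape, stride):
    N, Cin, L = x_shape
    F, CK = W.shape
    k = CK // Cin
    P = col.shape[1]
    dW = np.einsum("nfp,npq->fq", dout, col)
    db = dout.sum(axis=(0, 2))
    dcol = np.einsum("nfp,fq->npq", dout, W).reshape(N, P, Cin, k)
    dx = np.zeros(x_shape)
    for j in range(k):
        dx[:, :, j:j + stride * P:stride] += dcol[:, :, :, j].transpose(0, 2, 1)
    return dx, dW, db


class CNNClassifier:
    """Trainable 1-D CNN satisfying the binary classifier contract.

    ``fit`` consumes a :class:`~eegxai.containers.WindowSet`;
    ``predict_proba`` maps a (channels x L) window or a batch to the
    probability of the ictal class.
    """

    def __init__(self, n_channels: int, window_length: int,
                 arch: ArchConfig | None = None,
                 training: TrainingConfig | None = None):
        self.arch = arch or ArchConfig()
        self.training = training or TrainingConfig()
        self.n_channels = int(n_channels)
        self.window_length = int(window_length)
        if self.arch.siamese and self.n_channels % 2:
            raise ValueError("siamese branches need an even channel count")
        self._branch_channels = (self.n_channels // 2 if self.arch.siamese
                                 else self.n_channels)
        self._init_params()
        self._norm = (0.0, 1.0)

    # -- construction ------------------------------------------------------

    def _init_params(self) -> None:
        rng = np.random.default_rng(self.training.seed)
        a = self.arch
        params: dict[str, np.ndarray] = {}
        c_in, length = self._branch_channels, self.window_length
        for i, f in enumerate(a.conv_filters):
            fan_in = c_in * a.kernel_size
            params[f"Wc{i}"] = rng.normal(0, np.sqrt(2.0 / fan_in),
                                          (f, fan_in))
            params[f"bc{i}"] = np.zeros(f)
            length = (length - a.kernel_size) // a.stride + 1
            if length < 1:
                raise ValueError("window too short for the conv stack")
            c_in = f
        flat = c_in * length * (2 if a.siamese else 1)
        params["Wd1"] = rng.normal(0, np.sqrt(2.0 / flat), (a.dense_units, flat))
        params["bd1"] = np.zeros(a.dense_units)
        params["Wd2"] = rng.normal(0, np.sqrt(2.0 / a.dense_units),
                                   (2, a.dense_units))
        params["bd2"] = np.zeros(2)
        self.params = params
        self._conv_out = (c_in, length)

    # -- forward / backward ------------------------------------------------

    def _forward(self, x: np.ndarray, rng: np.random.Generator | None = None):
        """Logits for a batch; caches intermediates when training (rng given)."""
        a = self.arch
        N = x.shape[0]
        if a.siamese:
            x = x.reshape(N * 2, self._branch_channels, self.window_length)
        cache: dict = {"x0_shape": x.shape}
        h = x
        for i in range(len(a.conv_filters)):
            out, col = _conv_forward(h, self.params[f"Wc{i}"],
                                     self.params[f"bc{i}"], a.stride)
            mask = out > 0
            cache[f"col{i}"], cache[f"mask{i}"], cache[f"in{i}"] = col, mask, h.shape
            h = out * mask
        flat = h.reshape(N, -1)
        cache["flat_shape"] = h.shape
        z1 = flat @ self.params["Wd1"].T + self.params["bd1"]
        m1 = z1 > 0
        h1 = z1 * m1
        if rng is not None and a.dropout > 0:
            drop = (rng.random(h1.shape) >= a.dropout) / (1 - a.dropout)
        else:
            drop = np.ones_like(h1)
        h1d = h1 * drop
        logits = h1d @ self.params["Wd2"].T + self.params["bd2"]
        cache.update(flat=flat, m1=m1, h1d=h1d, drop=drop)
        return logits, cache

    def _backward(self, dlogits: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        a = self.arch
        grads: dict[str, np.ndarray] = {}
        grads["Wd2"] = dlogits.T @ cache["h1d"]
        grads["bd2"] = dlogits.sum(axis=0)
        dh1 = (dlogits @ self.params["Wd2"]) * cache["drop"] * cache["m1"]
        grads["Wd1"] = dh1.T @ cache["flat"]
        grads["bd1"] = dh1.sum(axis=0)
        dflat = dh1 @ self.params["Wd1"]
        dh = dflat.reshape(cache["flat_shape"])
        for i in reversed(range(len(a.conv_filters))):
            dh = dh * cache[f"mask{i}"]
            dh, dW, db = _conv_backward(dh, cache[f"col{i}"],
                                        self.params[f"Wc{i}"],
                                        cache[f"in{i}"], a.stride)
            grads[f"Wc{i}"], grads[f"bc{i}"] = dW, db
        return grads

    # -- public API --------------------------------------------------------

    def fit(self, windows, validation=None, verbose: bool = False):
        """Train with Adam on cross-entropy; seeded and deterministic.

        The validation set, if given, is only monitored (printed with
        ``verbose``); it never drives model selection or early stopping.
        """
        x = np.asarray(windows.data, dtype=np.float64)
        y = np.asarray(windows.labels, dtype=np.int64)
        mu, sd = float(x.mean()), float(x.std() or 1.0)
        self._norm = (mu, sd)
        x = (x - mu) / sd
        cfg = self.training
        rng = np.random.default_rng(cfg.seed + 1)
        opt = _Adam(self.params, cfg)
        n = len(x)
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                xb, yb = x[idx], y[idx]
                logits, cache = self._forward(xb, rng=rng)
                logits -= logits.max(axis=1, keepdims=True)
                p = np.exp(logits)
                p /= p.sum(axis=1, keepdims=True)
                onehot = np.eye(2)[yb]
                dlogits = (p - onehot) / len(xb)
                grads = self._backward(dlogits, cache)
                opt.step(self.params, grads)
            if verbose:
                acc = float(np.mean(self.predict(windows.data) == y))
                msg = f"epoch {epoch + 1}/{cfg.epochs} train_acc={acc:.3f}"
                if validation is not None and len(validation):
                    vacc = float(np.mean(
                        self.predict(validation.data) == validation.labels))
                    msg += f" val_acc={vacc:.3f}"
                print(msg)
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        single = x.ndim == 2
        if single:
            x = x[None]
        if x.shape[1:] != (self.n_channels, self.window_length):
            raise ValueError(
                f"expected windows of shape ({self.n_channels}, "
                f"{self.window_length}), got {x.shape[1:]}"
            )
        mu, sd = self._norm
        out = np.empty(len(x))
        for start in range(0, len(x), 512):
            xb = (x[start:start + 512] - mu) / sd
            logits, _ = self._forward(xb, rng=None)
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            out[start:start + 512] = (p[:, 1] / p.sum(axis=1))
        return out[0] if single else out

    def predict(self, x: np.ndarray) -> np.ndarray:
        return (np.atleast_1d(self.predict_proba(x)) >= 0.5).astype(int)


def build_reference_cnn(n_channels: int, window_length: int,
                        arch: ArchConfig | None = None,
                        training: TrainingConfig | None = None) -> CNNClassifier:
    """Construct the reference CNN for a given input shape."""
    return CNNClassifier(n_channels, window_length, arch=arch, training=training)
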