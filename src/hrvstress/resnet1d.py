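"""Modified 1D ResNet34 binary classifier for RR-interval segments.

A pure-NumPy implementation (forward and backward passes written out
explicitly) of a one-dimensional residual network:

* a convolutional stem — one 1D convolution, batch normalization, GELU,
  max pooling;
* 16 residual blocks in four stages (3 + 4 + 6 + 3, the ResNet34 stage
  counts), each block holding three 1D convolutions and two batch
  normalizations, with a kernel-size-1 convolution as the shortcut
  connection in every block;
* GELU activations throughout, batch normalization preceding each
  activation;
* global average pooling and a single-logit head, so the network emits a
  probability of the stress class via a sigmoid.

Inputs are fixed-length single-channel sequences — 1200 points for a 5-min
segment at 4 Hz, 240 points for a 1-min epoch — with shorter sequences
already tail-padded with zeros upstream. Padding is not masked: the network
sees the zero tail like any other pattern.

Training is plain minibatch Adam on binary cross-entropy with early stopping
on validation loss. Everything is deterministic given the seeds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

from .preprocess import Segment

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "ResNet1D",
    "TrainResult",
    "ModelConfigError",
    "TrainingDivergedError",
    "build_model",
    "train",
    "predict",
    "segments_to_xy",
]

logger = logging.getLogger(__name__)


class ModelConfigError(ValueError):
    """Raised for architecture hyperparameters that cannot produce a model."""


class TrainingDivergedError(RuntimeError):
    """Raised when the validation loss becomes non-finite."""


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters.

    ``stages`` is a sequence of (n_blocks, channels, first-block stride);
    the default reproduces the ResNet34 stage layout (3, 4, 6, 3 blocks at
    64/128/256/512 channels). Kernel sizes follow the canonical ResNet
    adapted to 1D: stem kernel 7 with stride 2 and a 3/2 max pool, block
    convolutions of kernel 3, 3 and 1.
    """

    input_len: int = 1200
    stem_kernel: int = 7
    stem_channels: int = 64
    stem_stride: int = 2
    pool_kernel: int = 3
    pool_stride: int = 2
    stages: Tuple[Tuple[int, int, int], ...] = (
        (3, 64, 1),
        (4, 128, 2),
        (6, 256, 2),
        (3, 512, 2),
    )

    @property
    def n_blocks(self) -> int:
        return sum(n for n, _, _ in self.stages)

    @classmethod
    def small(cls, input_len: int) -> "ModelSpec":
        """A reduced two-stage variant for quick experiments and tests."""
        return cls(
            input_len=input_len,
            stem_channels=8,
            stages=((1, 8, 1), (1, 16, 2)),
        )


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (binary cross-entropy loss, Adam)."""

    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not 0 < self.patience < self.max_epochs + 1:
            raise ValueError("patience must be in 1..max_epochs")


# ---------------------------------------------------------------------------
# Layers. Each layer caches what its backward pass needs during forward and
# exposes its parameters as (value, grad) pairs.
# ---------------------------------------------------------------------------


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Conv1d:
    """1D convolution with symmetric zero padding kernel//2."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        std = math.sqrt(2.0 / (c_in * kernel))  # He initialization
        self.W = Param(rng.normal(0.0, std, size=(c_out, c_in, kernel)))
        self.b = Param(np.zeros(c_out))
        self.kernel, self.stride, self.pad = kernel, stride, kernel // 2
        self._cache: tuple = ()

    @property
    def params(self) -> List[Param]:
        return [self.W, self.b]

    @staticmethod
    def out_len(length: int, kernel: int, stride: int, pad: int) -> int:
        return (length + 2 * pad - kernel) // stride + 1

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c_in, length = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        win = sliding_window_view(xp, self.kernel, axis=2)[:, :, :: self.stride, :]
        l_out = win.shape[2]
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(
            n * l_out, c_in * self.kernel
        )
        wmat = self.W.value.reshape(self.W.value.shape[0], -1)
        y = cols @ wmat.T + self.b.value
        self._cache = (cols, x.shape, l_out)
        return y.reshape(n, l_out, -1).transpose(0, 2, 1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape, l_out = self._cache
        n, c_in, length = x_shape
        c_out = dy.shape[1]
        dy2 = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(n * l_out, c_out)
        wmat = self.W.value.reshape(c_out, -1)
        self.W.grad += (dy2.T @ cols).reshape(self.W.value.shape)
        self.b.grad += dy2.sum(axis=0)
        dcols = (dy2 @ wmat).reshape(n, l_out, c_in, self.kernel)
        dxp = np.zeros((n, c_in, length + 2 * self.pad))
        for k in range(self.kernel):
            dxp[:, :, k : k + self.stride * (l_out - 1) + 1 : self.stride] += (
                dcols[:, :, :, k].transpose(0, 2, 1)
            )
        return dxp[:, :, self.pad : self.pad + length] if self.pad else dxp


class BatchNorm1d:
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps
        self._cache: tuple = ()

    @property
    def params(self) -> List[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None]) * inv_std[:, None]
        self._cache = (xhat, inv_std, training, x.shape)
        return self.gamma.value[:, None] * xhat + self.beta.value[:, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, training, shape = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2))
        self.beta.grad += dy.sum(axis=(0, 2))
        dxhat = dy * self.gamma.value[:, None]
        if not training:
            return dxhat * inv_std[:, None]
        m = shape[0] * shape[2]
        return (
            inv_std[:, None]
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=(0, 2), keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
            )
        )


class GELU:
    params: List[Param] = []

    def __init__(self):
        self._x: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return 0.5 * x * (1.0 + erf(x / math.sqrt(2.0)))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
        return dy * (cdf + x * pdf)


class MaxPool1d:
    params: List[Param] = []

    def __init__(self, kernel: int, stride: int):
        self.kernel, self.stride, self.pad = kernel, stride, kernel // 2
        self._cache: tuple = ()

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, length = x.shape
        xp = np.pad(
            x, ((0, 0), (0, 0), (self.pad, self.pad)), constant_values=-np.inf
        )
        win = sliding_window_view(xp, self.kernel, axis=2)[:, :, :: self.stride, :]
        idx = win.argmax(axis=3)
        y = np.take_along_axis(win, idx[..., None], axis=3)[..., 0]
        self._cache = (idx, x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, (n, c, length) = self._cache
        l_out = dy.shape[2]
        dxp = np.zeros((n, c, length + 2 * self.pad))
        pos = self.stride * np.arange(l_out)[None, None, :] + idx  # in padded coords
        ni = np.arange(n)[:, None, None]
        ci = np.arange(c)[None, :, None]
        np.add.at(dxp, (ni, ci, pos), dy)
        return dxp[:, :, self.pad : self.pad + length] if self.pad else dxp


class Linear:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        std = math.sqrt(1.0 / c_in)
        self.W = Param(rng.normal(0.0, std, size=(c_out, c_in)))
        self.b = Param(np.zeros(c_out))
        self._x: Optional[np.ndarray] = None

    @property
    def params(self) -> List[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value


class ResidualBlock:
    """conv(3)-BN-GELU-conv(3)-BN-GELU-conv(1), plus a conv(1) shortcut.

    Three convolutions and two batch normalizations on the main path; the
    shortcut is a kernel-size-1 convolution in every block (not only where
    channel count or stride changes). No further normalization or activation
    after the residual addition.
    """

    def __init__(self, c_in: int, c_out: int, stride: int, rng: np.random.Generator):
        self.conv1 = Conv1d(c_in, c_out, 3, stride, rng)
        self.bn1 = BatchNorm1d(c_out)
        self.act1 = GELU()
        self.conv2 = Conv1d(c_out, c_out, 3, 1, rng)
        self.bn2 = BatchNorm1d(c_out)
        self.act2 = GELU()
        self.conv3 = Conv1d(c_out, c_out, 1, 1, rng)
        self.shortcut = Conv1d(c_in, c_out, 1, stride, rng)
        self._main = [
            self.conv1, self.bn1, self.act1,
            self.conv2, self.bn2, self.act2,
            self.conv3,
        ]

    @property
    def params(self) -> List[Param]:
        out: List[Param] = []
        for layer in self._main + [self.shortcut]:
            out.extend(layer.params)
        return out

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        h = x
        for layer in self._main:
            h = layer.forward(h, training)
        return h + self.shortcut.forward(x, training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = self.shortcut.backward(dy)
        d = dy
        for layer in reversed(self._main):
            d = layer.backward(d)
        return dx + d


class ResNet1D:
    """The assembled network: stem, residual stages, pooled single-logit head."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.stem_conv = Conv1d(1, spec.stem_channels, spec.stem_kernel,
                                spec.stem_stride, rng)
        self.stem_bn = BatchNorm1d(spec.stem_channels)
        self.stem_act = GELU()
        self.stem_pool = MaxPool1d(spec.pool_kernel, spec.pool_stride)
        self.blocks: List[ResidualBlock] = []
        c_in = spec.stem_channels
        length = Conv1d.out_len(spec.input_len, spec.stem_kernel, spec.stem_stride,
                                spec.stem_kernel // 2)
        length = Conv1d.out_len(length, spec.pool_kernel, spec.pool_stride,
                                spec.pool_kernel // 2)
        if length < 1:
            raise ModelConfigError("input too short for the stem/pool strides")
        for n_blocks, channels, stride in spec.stages:
            for i in range(n_blocks):
                s = stride if i == 0 else 1
                length_next = Conv1d.out_len(length, 3, s, 1)
                if length_next < 1:
                    raise ModelConfigError(
                        f"temporal length collapses below 1 at stage stride {s}"
                    )
                self.blocks.append(ResidualBlock(c_in, channels, s, rng))
                c_in, length = channels, length_next
        self.head = Linear(c_in, 1, rng)
        self._layers = [self.stem_conv, self.stem_bn, self.stem_act,
                        self.stem_pool, *self.blocks]
        self._pool_len: Optional[int] = None

    @property
    def params(self) -> List[Param]:
        out: List[Param] = []
        for layer in self._layers:
            out.extend(layer.params)
        out.extend(self.head.params)
        return out

    @property
    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim == 2:
            x = x[:, None, :]
        if x.shape[2] != self.spec.input_len:
            raise ValueError(
                f"expected input length {self.spec.input_len}, got {x.shape[2]}"
            )
        h = x
        for layer in self._layers:
            h = layer.forward(h, training)
        self._pool_len = h.shape[2]
        pooled = h.mean(axis=2)  # global average pooling
        return self.head.forward(pooled, training)[:, 0]

    def backward_logits(self, dlogit: np.ndarray) -> None:
        d = self.head.backward(dlogit[:, None])
        d = np.repeat(d[:, :, None], self._pool_len, axis=2) / self._pool_len
        for layer in reversed(self._layers):
            d = layer.backward(d)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        if x.ndim == 2:
            x = x[:, None, :]
        # clip logits so extreme pre-training activations cannot underflow the
        # sigmoid to an exact 0 or 1
        out = [
            _sigmoid(np.clip(
                self.forward_logits(x[i : i + batch_size], training=False),
                -500.0, 500.0,
            ))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(out) if out else np.empty(0)

    def get_weights(self) -> List[np.ndarray]:
        state = [p.value.copy() for p in self.params]
        for layer in self._layers:
            if isinstance(layer, BatchNorm1d):
                state.append(layer.running_mean.copy())
                state.append(layer.running_var.copy())
        for block in self.blocks:
            for bn in (block.bn1, block.bn2):
                state.append(bn.running_mean.copy())
                state.append(bn.running_var.copy())
        return state

    def set_weights(self, state: Sequence[np.ndarray]) -> None:
        it = iter(state)
        for p in self.params:
            p.value[...] = next(it)
        for layer in self._layers:
            if isinstance(layer, BatchNorm1d):
                layer.running_mean[...] = next(it)
                layer.running_var[...] = next(it)
        for block in self.blocks:
            for bn in (block.bn1, block.bn2):
                bn.running_mean[...] = next(it)
                bn.running_var[...] = next(it)

    def zero_head(self) -> None:
        """Zero the output head; the sigmoid then emits exactly 0.5 everywhere."""
        self.head.W.value[...] = 0.0
        self.head.b.value[...] = 0.0


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                    np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean binary cross-entropy from raw logits; returns (loss, dloss/dlogits)."""
    # softplus(z) - y*z, computed stably
    loss = np.mean(np.logaddexp(0.0, logits) - y * logits)
    grad = (_sigmoid(logits) - y) / len(y)
    return float(loss), grad


class Adam:
    def __init__(self, params: List[Param], lr: float,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad**2 - v)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------


def build_model(spec: ModelSpec, seed: int = 0) -> ResNet1D:
    """Instantiate the network; raises ModelConfigError for impossible specs."""
    model = ResNet1D(spec, seed=seed)
    logger.info("built 1D ResNet: %d residual blocks, %d parameters",
                len(model.blocks), model.n_parameters)
    return model


def segments_to_xy(
    segments: Sequence[Segment], positive_label: str
) -> Tuple[np.ndarray, np.ndarray]:
    """Stack segment value vectors and binarize labels (positive_label -> 1)."""
    x = np.stack([s.values for s in segments])
    y = np.array([1.0 if s.label == positive_label else 0.0 for s in segments])
    return x, y


@dataclass
class TrainResult:
    model: ResNet1D
    train_loss: List[float]
    val_loss: List[float]
    best_epoch: int

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"epoch": np.arange(1, len(self.train_loss) + 1),
             "train_loss": self.train_loss, "val_loss": self.val_loss}
        )


DataLike = Union[Sequence[Segment], Tuple[np.ndarray, np.ndarray]]


def _as_xy(data: DataLike, positive_label: Optional[str]) -> Tuple[np.ndarray, np.ndarray]:
    if isinstance(data, tuple):
        return data
    if positive_label is None:
        raise ValueError("positive_label required when passing Segment lists")
    return segments_to_xy(data, positive_label)


def train(
    model: ResNet1D,
    train_segments: DataLike,
    val_segments: DataLike,
    cfg: TrainConfig,
    positive_label: Optional[str] = None,
) -> TrainResult:
    """Minibatch Adam on BCE with early stopping at the best validation loss.

    Participant-disjointness of train and validation sets is the caller's
    responsibility (enforced by the cross-validation fold plans).
    """
    x_tr, y_tr = _as_xy(train_segments, positive_label)
    x_va, y_va = _as_xy(val_segments, positive_label)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params, cfg.learning_rate)
    best_val = np.inf
    best_state = model.get_weights()
    best_epoch = 0
    train_hist: List[float] = []
    val_hist: List[float] = []
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(x_tr))
        epoch_loss = 0.0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            model.zero_grad()
            logits = model.forward_logits(x_tr[idx], training=True)
            loss, dlogits = bce_with_logits(logits, y_tr[idx])
            model.backward_logits(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
        train_hist.append(epoch_loss / len(x_tr))
        val_logits = model.forward_logits(x_va, training=False)
        val_loss, _ = bce_with_logits(val_logits, y_va)
        val_hist.append(val_loss)
        if not np.isfinite(val_loss):
            raise TrainingDivergedError(f"validation loss {val_loss} at epoch {epoch}")
        if val_loss < best_val - 1e-12:
            best_val, best_epoch = val_loss, epoch
            best_state = model.get_weights()
        elif epoch - best_epoch >= cfg.patience:
            break
    model.set_weights(best_state)
    logger.info("training stopped at epoch %d (best val loss %.4f at epoch %d)",
                len(train_hist), best_val, best_epoch)
    return TrainResult(model, train_hist, val_hist, best_epoch)


def predict(
    model: ResNet1D,
    segments: DataLike,
    positive_label: Optional[str] = None,
) -> np.ndarray:
    """Per-segment probability of the positive class (order-preserving)."""
    if isinstance(segments, tuple):
        x = segments[0]
    elif len(segments) and isinstance(segments[0], Segment):
        x = np.stack([s.values for s in segments])
    else:
        x = np.asarray(segments)
    return model.predict_proba(x)
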