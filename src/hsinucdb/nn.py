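"""Compact CPU convolutional-network engine for the segmentation models.

Implements exactly what the encoder–decoder segmentation heads need —
stride-1 "same" convolutions in 2-D and 3-D (via ``sliding_window_view`` +
BLAS contractions), average pooling, nearest-neighbour upsampling, skip
concatenation, weighted softmax cross-entropy and Adam — with hand-written
exact gradients.  All randomness flows through explicit
``numpy.random.Generator`` objects, so training is bit-reproducible.

Layout conventions: 2-D tensors are ``(N, C, H, W)``; 3-D (spatio-spectral)
tensors are ``(N, C, H, W, B)`` with the spectral axis last.  The spectral
axis is padded in ``edge`` mode so a cube that is constant along wavelength
stays constant through every convolution (the spectral-collapse identity).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np


# --------------------------------------------------------------------------
# convolution primitives
# --------------------------------------------------------------------------

def _pad_spatial(x: np.ndarray, pads: Sequence[int], modes: Sequence[str]) -> np.ndarray:
    """Pad the spatial axes (all but the first two) one axis at a time."""
    for ax, (p, mode) in enumerate(zip(pads, modes), start=2):
        if p == 0:
            continue
        width = [(0, 0)] * x.ndim
        width[ax] = (p, p)
        x = np.pad(x, width, mode=mode)
    return x


def conv_same_forward(
    x: np.ndarray, W: np.ndarray, b: np.ndarray, modes: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Stride-1 same convolution; returns (out, padded input for backward).

    ``x`` is ``(N, C, *S)``, ``W`` is ``(O, C, *K)`` with odd kernel sizes.
    Computed as one small GEMM per kernel tap, which keeps peak memory at
    the size of the activation instead of materializing an im2col matrix.
    """
    d = W.ndim - 2
    K = W.shape[2:]
    pads = [(k - 1) // 2 for k in K]
    xp = _pad_spatial(x, pads, modes)
    S = x.shape[2:]
    acc = None
    for idx in np.ndindex(*K):
        sl = tuple(slice(i, i + s) for i, s in zip(idx, S))
        xs = xp[(slice(None), slice(None)) + sl]
        t = np.tensordot(xs, W[(slice(None), slice(None)) + idx], axes=([1], [1]))
        acc = t if acc is None else acc + t  # (N, *S, O)
    out = np.moveaxis(acc, -1, 1) + b.reshape((1, -1) + (1,) * d)
    return np.ascontiguousarray(out), xp


def conv_same_backward(
    dY: np.ndarray,
    xp: np.ndarray,
    W: np.ndarray,
    modes: Sequence[str],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of :func:`conv_same_forward` (exact for both pad modes)."""
    d = W.ndim - 2
    K = W.shape[2:]
    pads = [(k - 1) // 2 for k in K]
    S = tuple(s - 2 * p for s, p in zip(xp.shape[2:], pads))
    sp_axes = tuple(range(2, 2 + d))
    db = dY.sum(axis=(0,) + sp_axes)
    dW = np.zeros_like(W)
    dxp = np.zeros_like(xp)
    dYm = np.moveaxis(dY, 1, -1)  # (N, *S, O)
    for idx in np.ndindex(*K):
        sl = tuple(slice(i, i + s) for i, s in zip(idx, S))
        xs = xp[(slice(None), slice(None)) + sl]
        dW[(slice(None), slice(None)) + idx] = np.tensordot(
            dY, xs, axes=((0,) + sp_axes, (0,) + sp_axes)
        )
        g = np.tensordot(dYm, W[(slice(None), slice(None)) + idx], axes=([-1], [0]))
        dxp[(slice(None), slice(None)) + sl] += np.moveaxis(g, -1, 1)

    # fold padding gradients back onto the unpadded input and crop
    for ax, (p, mode) in enumerate(zip(pads, modes), start=2):
        if p == 0:
            continue
        if mode == "edge":
            head = [slice(None)] * dxp.ndim
            head[ax] = slice(0, p)
            first = [slice(None)] * dxp.ndim
            first[ax] = slice(p, p + 1)
            dxp[tuple(first)] += dxp[tuple(head)].sum(axis=ax, keepdims=True)
            tail = [slice(None)] * dxp.ndim
            tail[ax] = slice(dxp.shape[ax] - p, None)
            last = [slice(None)] * dxp.ndim
            last[ax] = slice(dxp.shape[ax] - p - 1, dxp.shape[ax] - p)
            dxp[tuple(last)] += dxp[tuple(tail)].sum(axis=ax, keepdims=True)
        sl = [slice(None)] * dxp.ndim
        sl[ax] = slice(p, dxp.shape[ax] - p)
        dxp = dxp[tuple(sl)]
    return np.ascontiguousarray(dxp), dW, db


# --------------------------------------------------------------------------
# layers
# --------------------------------------------------------------------------

class Layer:
    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dY: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv(Layer):
    """Stride-1 same convolution (He-initialized)."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: Sequence[int],
        rng: np.random.Generator,
        pad_modes: Optional[Sequence[str]] = None,
        dtype: type = np.float32,
    ) -> None:
        kernel = tuple(kernel)
        if any(k % 2 == 0 for k in kernel):
            raise ValueError("kernel sizes must be odd")
        fan_in = c_in * int(np.prod(kernel))
        scale = np.sqrt(2.0 / fan_in)
        self.W = (scale * rng.standard_normal((c_out, c_in) + kernel)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.modes = list(pad_modes) if pad_modes else ["constant"] * len(kernel)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]
        self._xp: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        out, self._xp = conv_same_forward(x, self.W, self.b, self.modes)
        return out

    def backward(self, dY: np.ndarray) -> np.ndarray:
        dX, dW, db = conv_same_backward(dY, self._xp, self.W, self.modes)
        self.dW += dW
        self.db += db
        self._xp = None
        return dX


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dY: np.ndarray) -> np.ndarray:
        return dY * self._mask


class AvgPool(Layer):
    """Block average pooling with per-axis factors (spatial axes only)."""

    def __init__(self, factors: Sequence[int]) -> None:
        self.factors = tuple(factors)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        shape = list(x.shape[:2])
        for s, f in zip(x.shape[2:], self.factors):
            if s % f:
                raise ValueError(f"axis of size {s} not divisible by pool factor {f}")
            shape += [s // f, f]
        xr = x.reshape(shape)
        axes = tuple(range(3, 3 + 2 * len(self.factors), 2))
        return xr.mean(axis=axes)

    def backward(self, dY: np.ndarray) -> np.ndarray:
        scale = 1.0 / np.prod(self.factors)
        out = dY * scale
        for ax, f in enumerate(self.factors, start=2):
            out = np.repeat(out, f, axis=ax)
        return out.reshape(self._in_shape)


class Upsample(Layer):
    """Nearest-neighbour upsampling with per-axis factors."""

    def __init__(self, factors: Sequence[int]) -> None:
        self.factors = tuple(factors)

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = x
        for ax, f in enumerate(self.factors, start=2):
            out = np.repeat(out, f, axis=ax)
        return out

    def backward(self, dY: np.ndarray) -> np.ndarray:
        out = dY
        for ax, f in enumerate(self.factors, start=2):
            shape = list(out.shape)
            shape[ax : ax + 1] = [shape[ax] // f, f]
            out = out.reshape(shape).sum(axis=ax + 1)
        return out


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]) -> None:
        self.layers = list(layers)
        self.params = [p for l in self.layers for p in l.params]
        self.grads = [g for l in self.layers for g in l.grads]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dY: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dY = l.backward(dY)
        return dY


def _conv_block(
    c_in: int,
    c_out: int,
    kernel: Sequence[int],
    rng: np.random.Generator,
    pad_modes: Optional[Sequence[str]],
    dtype: type,
) -> Sequential:
    return Sequential(
        [
            Conv(c_in, c_out, kernel, rng, pad_modes, dtype),
            ReLU(),
            Conv(c_out, c_out, kernel, rng, pad_modes, dtype),
            ReLU(),
        ]
    )


# --------------------------------------------------------------------------
# U-Net models
# --------------------------------------------------------------------------

class UNet2D:
    """Small one-skip encoder–decoder for 3-class patch segmentation."""

    def __init__(
        self,
        in_channels: int = 3,
        n_classes: int = 3,
        width: int = 8,
        seed: int = 0,
        dtype: type = np.float32,
    ) -> None:
        rng = np.random.default_rng(seed)
        k = (3, 3)
        self.enc1 = _conv_block(in_channels, width, k, rng, None, dtype)
        self.pool = AvgPool((2, 2))
        self.enc2 = _conv_block(width, 2 * width, k, rng, None, dtype)
        self.up = Upsample((2, 2))
        self.dec1 = _conv_block(3 * width, width, k, rng, None, dtype)
        self.head = Conv(width, n_classes, (1, 1), rng, None, dtype)
        self.blocks = [self.enc1, self.enc2, self.dec1, self.head]
        self.n_classes = n_classes
        self.in_channels = in_channels

    def forward(self, x: np.ndarray) -> np.ndarray:
        e1 = self.enc1.forward(x)
        e2 = self.enc2.forward(self.pool.forward(e1))
        u = self.up.forward(e2)
        cat = np.concatenate([u, e1], axis=1)
        d = self.dec1.forward(cat)
        return self.head.forward(d)

    def backward(self, dY: np.ndarray) -> None:
        d = self.head.backward(dY)
        dcat = self.dec1.backward(d)
        c2 = dcat.shape[1] - self.enc1.layers[-2].W.shape[0]
        du, de1_skip = dcat[:, :c2], dcat[:, c2:]
        de2 = self.up.backward(du)
        dp = self.enc2.backward(de2)
        de1 = self.pool.backward(dp) + de1_skip
        self.enc1.backward(de1)

    @property
    def params(self) -> list[np.ndarray]:
        return [p for b in self.blocks for p in b.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for b in self.blocks for g in b.grads]


class CollapseUNet3D:
    """3-D spatio-spectral U-Net with a spectral-collapse head.

    The encoder/decoder apply 3-D convolutions over (y, x, wavelength) with
    spatial-only pooling; after the last decoder convolution the feature
    maps are averaged along the spectral axis (adaptive average pooling to
    spectral length 1) and a 2-D 1x1 convolution projects to class logits,
    so a 3-D input yields a 2-D multi-class map at full spatial resolution.
    """

    def __init__(
        self,
        n_bands: int,
        in_channels: int = 1,
        n_classes: int = 3,
        width: int = 4,
        seed: int = 0,
        dtype: type = np.float32,
    ) -> None:
        if n_bands < 1:
            raise ValueError("need at least one spectral band")
        rng = np.random.default_rng(seed)
        k = (3, 3, 3)
        modes = ["constant", "constant", "edge"]
        self.enc1 = _conv_block(in_channels, width, k, rng, modes, dtype)
        self.pool = AvgPool((2, 2, 1))
        self.enc2 = _conv_block(width, 2 * width, k, rng, modes, dtype)
        self.up = Upsample((2, 2, 1))
        self.dec1 = _conv_block(3 * width, width, k, rng, modes, dtype)
        self.head = Conv(width, n_classes, (1, 1), rng, None, dtype)
        self.blocks = [self.enc1, self.enc2, self.dec1, self.head]
        self.n_bands = n_bands
        self.n_classes = n_classes
        self.in_channels = in_channels

    def forward(self, x: np.ndarray, return_features: bool = False):
        if x.shape[-1] != self.n_bands:
            raise ValueError(
                f"input has {x.shape[-1]} bands, model expects {self.n_bands}"
            )
        e1 = self.enc1.forward(x)
        e2 = self.enc2.forward(self.pool.forward(e1))
        u = self.up.forward(e2)
        cat = np.concatenate([u, e1], axis=1)
        d = self.dec1.forward(cat)
        self._bands = d.shape[-1]
        collapsed = d.mean(axis=-1)  # adaptive average pool -> spectral length 1
        logits = self.head.forward(collapsed)
        if return_features:
            return logits, d
        return logits

    def backward(self, dY: np.ndarray) -> None:
        dcollapsed = self.head.backward(dY)
        dd = np.repeat(dcollapsed[..., None], self._bands, axis=-1) / self._bands
        dcat = self.dec1.backward(dd)
        c2 = dcat.shape[1] - self.enc1.layers[-2].W.shape[0]
        du, de1_skip = dcat[:, :c2], dcat[:, c2:]
        de2 = self.up.backward(du)
        dp = self.enc2.backward(de2)
        de1 = self.pool.backward(dp) + de1_skip
        self.enc1.backward(de1)

    @property
    def params(self) -> list[np.ndarray]:
        return [p for b in self.blocks for p in b.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for b in self.blocks for g in b.grads]

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))


# --------------------------------------------------------------------------
# loss, optimizer, training loop
# --------------------------------------------------------------------------

def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray, targets: np.ndarray, class_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Per-pixel class-weighted softmax cross-entropy.

    ``logits`` is ``(N, C, *S)``, ``targets`` integer ``(N, *S)``.  Returns
    the scalar loss (weighted mean) and the gradient w.r.t. the logits.
    """
    p = softmax(logits.astype(np.float64), axis=1)
    w = np.asarray(class_weights, dtype=np.float64)[targets]
    idx = np.expand_dims(targets, 1)
    p_t = np.take_along_axis(p, idx, axis=1)[:, 0]
    total_w = w.sum()
    loss = float(-(w * np.log(np.clip(p_t, 1e-12, None))).sum() / total_w)
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, idx, 1.0, axis=1)
    dlogits = (p - onehot) * np.expand_dims(w, 1) / total_w
    return loss, dlogits.astype(logits.dtype)


def inverse_frequency_weights(targets: np.ndarray, n_classes: int) -> np.ndarray:
    """Inverse class-pixel-frequency weights, normalized to mean 1."""
    counts = np.bincount(np.asarray(targets).ravel(), minlength=n_classes).astype(float)
    counts = np.maximum(counts, 1.0)
    w = counts.sum() / counts
    return w / w.mean()


class Adam:
    def __init__(self, params: Sequence[np.ndarray], grads: Sequence[np.ndarray], lr: float = 1e-3):
        self.params = list(params)
        self.grads = list(grads)
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p, dtype=np.float64) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g.astype(np.float64) ** 2
            p -= (self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)).astype(p.dtype)

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_score: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_score: float = -np.inf


def fit_segmentation_model(
    model,
    train_x: np.ndarray,
    train_y: np.ndarray,
    cfg,
    val_fn: Optional[Callable[[], float]] = None,
    class_weights: Optional[np.ndarray] = None,
) -> TrainHistory:
    """Mini-batch Adam training with best-checkpoint selection.

    ``val_fn`` returns the model-selection score (validation nuclei Dice);
    the parameters of the best-scoring epoch are restored at the end.
    ``cfg`` needs ``epochs``, ``batch_size``, ``learning_rate``, ``seed``.
    """
    n = train_x.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    if class_weights is None:
        class_weights = inverse_frequency_weights(train_y, model.n_classes)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params, model.grads, lr=cfg.learning_rate)
    history = TrainHistory()
    best_params = None
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = train_x[idx]
            yb = train_y[idx]
            opt.zero_grad()
            logits = model.forward(xb)
            loss, dlogits = weighted_cross_entropy(logits, yb, class_weights)
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history.train_loss.append(float(np.mean(losses)))
        if val_fn is not None:
            score = float(val_fn())
            history.val_score.append(score)
            if score > history.best_score:
                history.best_score = score
                history.best_epoch = epoch
                best_params = [p.copy() for p in model.params]
    if best_params is not None:
        for p, bp in zip(model.params, best_params):
            p[...] = bp
    return history
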