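"""Minimal neural-network primitives on numpy arrays.

Trainable pieces (linear maps, MLP heads) carry explicit analytic
backward passes; the convolutional pyramid used as a frozen feature
extractor is forward-only.  Everything is float64 for the benefit of
finite-difference gradient checks.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "Param",
    "Linear",
    "MLP",
    "SGDMomentum",
    "kaiming",
    "softmax_rows",
    "conv2d",
    "avgpool2",
    "upsample2",
    "roi_align",
]


def kaiming(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    """He-normal initialisation for ReLU networks."""
    return rng.normal(0.0, np.sqrt(2.0 / max(fan_in, 1)), size=shape)


class Param:
    """A trainable array with an accumulated gradient buffer."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Linear:
    """y = x W (+ b).  Bias optional; attention projections use none."""

    def __init__(self, rng, d_in: int, d_out: int, bias: bool = True):
        self.W = Param(kaiming(rng, d_in, (d_in, d_out)))
        self.b = Param(np.zeros(d_out)) if bias else None

    def forward(self, x: np.ndarray):
        y = x @ self.W.value
        if self.b is not None:
            y = y + self.b.value
        return y, x

    def backward(self, grad_y: np.ndarray, cache) -> np.ndarray:
        x = cache
        self.W.grad += x.T @ grad_y
        if self.b is not None:
            self.b.grad += grad_y.sum(axis=0)
        return grad_y @ self.W.value.T

    def params(self):
        return [self.W] if self.b is None else [self.W, self.b]


class MLP:
    """Fully connected stack with ReLU between layers (none after last)."""

    def __init__(self, rng, dims: list[int], bias: bool = True):
        self.layers = [
            Linear(rng, dims[i], dims[i + 1], bias=bias) for i in range(len(dims) - 1)
        ]

    def forward(self, x: np.ndarray):
        caches = []
        for i, layer in enumerate(self.layers):
            x, c = layer.forward(x)
            relu_mask = None
            if i < len(self.layers) - 1:
                relu_mask = x > 0
                x = x * relu_mask
            caches.append((c, relu_mask))
        return x, caches

    def backward(self, grad_y: np.ndarray, caches) -> np.ndarray:
        for layer, (c, relu_mask) in zip(reversed(self.layers), reversed(caches)):
            if relu_mask is not None:
                grad_y = grad_y * relu_mask
            grad_y = layer.backward(grad_y, c)
        return grad_y

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class SGDMomentum:
    """SGD with classical momentum and decoupled L2 weight decay."""

    def __init__(self, params, lr: float, momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            g = p.grad + self.weight_decay * p.value
            v *= self.momentum
            v += g
            p.value -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def state(self):
        return [v.copy() for v in self.velocity]

    def load_state(self, state) -> None:
        self.velocity = [np.asarray(v, dtype=float) for v in state]


def softmax_rows(s: np.ndarray) -> np.ndarray:
    """Numerically stable row softmax."""
    s = np.asarray(s, dtype=float)
    return np.exp(s - logsumexp(s, axis=-1, keepdims=True))


# ---------------------------------------------------------------------------
# Forward-only spatial ops for the frozen backbone / RoI pooling
# ---------------------------------------------------------------------------


def conv2d(x: np.ndarray, w: np.ndarray, stride: int = 1) -> np.ndarray:
    """'Same'-padded 2-D convolution via im2col.

    x: (H, W, Cin); w: (k, k, Cin, Cout).  Forward-only (frozen weights).
    """
    k = w.shape[0]
    pad = k // 2
    xp = np.pad(x, ((pad, pad), (pad, pad), (0, 0)))
    H, W = x.shape[:2]
    # gather k*k shifted views
    cols = np.empty((H, W, k * k * x.shape[2]))
    idx = 0
    cin = x.shape[2]
    for dy in range(k):
        for dx in range(k):
            cols[:, :, idx * cin : (idx + 1) * cin] = xp[dy : dy + H, dx : dx + W, :]
            idx += 1
    out = cols.reshape(H * W, -1) @ w.reshape(-1, w.shape[-1])
    out = out.reshape(H, W, w.shape[-1])
    if stride > 1:
        out = out[::stride, ::stride]
    return out


def avgpool2(x: np.ndarray) -> np.ndarray:
    """2x2 average pooling (trailing odd row/col dropped)."""
    H, W = x.shape[:2]
    H2, W2 = H // 2, W // 2
    x = x[: 2 * H2, : 2 * W2]
    return x.reshape(H2, 2, W2, 2, -1).mean(axis=(1, 3))


def upsample2(x: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour 2x upsample, cropped/padded to ``out_hw``."""
    up = np.repeat(np.repeat(x, 2, axis=0), 2, axis=1)
    H, W = out_hw
    if up.shape[0] < H or up.shape[1] < W:
        up = np.pad(up, ((0, max(0, H - up.shape[0])), (0, max(0, W - up.shape[1])), (0, 0)), mode="edge")
    return up[:H, :W]


def roi_align(fmap: np.ndarray, boxes_xyxy: np.ndarray, out_size: int, spatial_scale: float) -> np.ndarray:
    """Bilinear RoI-Align of boxes to ``out_size`` x ``out_size`` grids.

    One sample per bin (bin centre), matching the single-sample RoI-Align
    variant.  ``spatial_scale`` maps image pixels to feature-map cells.
    Accepts one box (4,) or a batch (N, 4); returns (S, S, C) or (N, S, S, C).
    """
    H, W = fmap.shape[:2]
    b = np.asarray(boxes_xyxy, dtype=float)
    single = b.ndim == 1
    b = b.reshape(-1, 4) * spatial_scale
    w = np.maximum(b[:, 2] - b[:, 0], 1e-3)
    h = np.maximum(b[:, 3] - b[:, 1], 1e-3)
    steps = (np.arange(out_size) + 0.5) / out_size
    xs = b[:, 0, None] + steps[None, :] * w[:, None]  # (N, S)
    ys = b[:, 1, None] + steps[None, :] * h[:, None]
    xs = np.clip(xs - 0.5, 0, W - 1)
    ys = np.clip(ys - 0.5, 0, H - 1)
    x0 = np.floor(xs).astype(int)
    y0 = np.floor(ys).astype(int)
    x1i = np.minimum(x0 + 1, W - 1)
    y1i = np.minimum(y0 + 1, H - 1)
    fx = (xs - x0)[:, None, :, None]  # (N, 1, S, 1)
    fy = (ys - y0)[:, :, None, None]  # (N, S, 1, 1)
    f00 = fmap[y0[:, :, None], x0[:, None, :]]  # (N, S, S, C)
    f01 = fmap[y0[:, :, None], x1i[:, None, :]]
    f10 = fmap[y1i[:, :, None], x0[:, None, :]]
    f11 = fmap[y1i[:, :, None], x1i[:, None, :]]
    out = (
        f00 * (1 - fy) * (1 - fx)
        + f01 * (1 - fy) * fx
        + f10 * fy * (1 - fx)
        + f11 * fy * fx
    )
    return out[0] if single else out
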