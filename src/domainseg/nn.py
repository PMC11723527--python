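"""Minimal NumPy building blocks for the residual dilated CNN.

Stride-1 'same' 2D convolutions are computed as sliding-window views
contracted with :func:`numpy.tensordot` (im2col without the copy), with
hand-written backward passes. Everything runs in float32 on CPU and is fully
deterministic given the seeds supplied by the caller.
"""

from __future__ import annotations

import numpy as np


def _pad(x: np.ndarray, pad: int) -> np.ndarray:
    return np.pad(x, ((0, 0), (pad, pad), (pad, pad)))


def _shifted(xp: np.ndarray, i: int, j: int, dilation: int, H: int, W: int) -> np.ndarray:
    """Contiguous (cin, H·W) slab of the padded input shifted by kernel tap (i, j)."""
    view = xp[:, i * dilation : i * dilation + H, j * dilation : j * dilation + W]
    return np.ascontiguousarray(view).reshape(xp.shape[0], -1)


def _correlate(x: np.ndarray, weight: np.ndarray, dilation: int) -> np.ndarray:
    """'same' cross-correlation: x (cin,H,W) × weight (cout,cin,k,k) → (cout,H,W).

    Computed as k² shifted 1×1 matmuls (BLAS sgemm) rather than an im2col
    materialization — faster and far lighter on memory at 500×500.
    """
    cout, cin, k, _ = weight.shape
    _, H, W = x.shape
    if k == 1:
        return (weight[:, :, 0, 0] @ x.reshape(cin, -1)).reshape(cout, H, W)
    pad = dilation * (k - 1) // 2
    xp = _pad(x, pad)
    out = np.zeros((cout, H * W), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            out += weight[:, :, i, j] @ _shifted(xp, i, j, dilation, H, W)
    return out.reshape(cout, H, W)


class Conv2d:
    """Stride-1 'same' convolution with optional dilation."""

    def __init__(self, cin: int, cout: int, kernel: int, dilation: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("odd kernels only")
        scale = np.sqrt(2.0 / (cin * kernel * kernel))  # He init
        self.weight = (rng.standard_normal((cout, cin, kernel, kernel)) * scale).astype(np.float32)
        self.bias = np.zeros(cout, dtype=np.float32)
        self.dilation = dilation
        self.g_weight = np.zeros_like(self.weight)
        self.g_bias = np.zeros_like(self.bias)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, cache: bool) -> np.ndarray:
        if cache:
            self._x = x
        return _correlate(x, self.weight, self.dilation) + self.bias[:, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        cout, cin, k, _ = self.weight.shape
        _, H, W = gy.shape
        gy_flat = gy.reshape(cout, -1)
        self.g_bias += gy_flat.sum(axis=1)
        if k == 1:
            self.g_weight += (gy_flat @ x.reshape(cin, -1).T)[:, :, None, None]
        else:
            pad = self.dilation * (k - 1) // 2
            xp = _pad(x, pad)
            for i in range(k):
                for j in range(k):
                    self.g_weight[:, :, i, j] += gy_flat @ _shifted(
                        xp, i, j, self.dilation, H, W
                    ).T
        # gradient w.r.t. input: correlate gy with the rotated, transposed kernel
        w_rot = self.weight[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        self._x = None
        return _correlate(gy, np.ascontiguousarray(w_rot), self.dilation)

    def zero_grad(self) -> None:
        self.g_weight.fill(0.0)
        self.g_bias.fill(0.0)

    def parameters(self):
        return [(self.weight, self.g_weight), (self.bias, self.g_bias)]


class Dropout:
    """Inverted dropout; identity in eval mode."""

    def __init__(self, ratio: float):
        if not 0 <= ratio < 1:
            raise ValueError("dropout ratio must be in [0, 1)")
        self.ratio = ratio
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        if not train or self.ratio == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.ratio
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return gy
        gy = gy * self._mask
        self._mask = None
        return gy


class ResidualBlock:
    """conv → relu → conv, added to a (channel-adapted) skip, then relu.

    When the block narrows the channel count the skip is sliced to the first
    ``cout`` channels; widening zero-pads. Both adaptations are parameter-free
    so they do not add convolutional layers.
    """

    def __init__(self, cin: int, cout: int, kernel: int, dilation: int, rng: np.random.Generator):
        self.cin, self.cout = cin, cout
        self.conv1 = Conv2d(cin, cout, kernel, dilation, rng)
        self.conv2 = Conv2d(cout, cout, kernel, dilation, rng)
        self._h1_pos: np.ndarray | None = None
        self._y_pos: np.ndarray | None = None

    def _skip(self, x: np.ndarray) -> np.ndarray:
        if self.cout == self.cin:
            return x
        if self.cout < self.cin:
            return x[: self.cout]
        pad = np.zeros((self.cout - self.cin, *x.shape[1:]), dtype=x.dtype)
        return np.concatenate([x, pad], axis=0)

    def forward(self, x: np.ndarray, cache: bool) -> np.ndarray:
        h1 = np.maximum(self.conv1.forward(x, cache), 0.0)
        y = np.maximum(self._skip(x) + self.conv2.forward(h1, cache), 0.0)
        if cache:
            self._h1_pos = h1 > 0
            self._y_pos = y > 0
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = gy * self._y_pos
        gh1 = self.conv2.backward(g) * self._h1_pos
        gx = self.conv1.backward(gh1)
        # skip-path gradient
        if self.cout == self.cin:
            gx += g
        elif self.cout < self.cin:
            gx[: self.cout] += g
        else:
            gx += g[: self.cin]
        self._h1_pos = self._y_pos = None
        return gx

    def zero_grad(self) -> None:
        self.conv1.zero_grad()
        self.conv2.zero_grad()

    def parameters(self):
        return self.conv1.parameters() + self.conv2.parameters()


class Adam:
    """Adam over a flat list of (param, grad) pairs, updated in place."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
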