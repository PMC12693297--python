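"""Minimal explicit-backprop neural layers (numpy, NCHW layout).

Each layer exposes ``forward(x)`` (caching what backward needs),
``backward(grad_out)`` (returning grad w.r.t. the input and filling
``.grads``), and ``params`` / ``grads`` lists of arrays updated in place
by the optimizer. Convolutions use im2col so the heavy lifting is one
BLAS matmul per layer. Shapes are small by design: the stack targets
libraries of tens of images on a single CPU.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2D", "ReLU", "MaxPool2", "GlobalAvgPool", "Dense"]


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """3×3-style 'same' convolution, stride 1, He-initialized."""

    def __init__(self, cin: int, cout: int, k: int = 3, rng: np.random.Generator | None = None):
        super().__init__()
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for same-padding")
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * k * k))
        self.w = (rng.standard_normal((cout, cin, k, k)) * scale).astype(np.float64)
        self.b = np.zeros(cout)
        self.k, self.cin, self.cout = k, cin, cout
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (n, c, h, w, k, k) -> (n*h*w, c*k*k)
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * self.k * self.k)
        wmat = self.w.reshape(self.cout, -1)
        out = cols @ wmat.T + self.b
        self._cache = (cols, x.shape)
        return out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        cols, (n, c, h, w) = self._cache
        g = grad_out.transpose(0, 2, 3, 1).reshape(n * h * w, self.cout)
        self.grads[0][...] = (g.T @ cols).reshape(self.w.shape)
        self.grads[1][...] = g.sum(axis=0)
        dcols = g @ self.w.reshape(self.cout, -1)  # (n*h*w, c*k*k)
        dcols = dcols.reshape(n, h, w, c, self.k, self.k)
        p = self.k // 2
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, p : p + h, p : p + w]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out * self._mask


class MaxPool2(Layer):
    """2×2 max pooling, stride 2; requires even spatial dimensions."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2 needs even spatial dims, got {(h, w)}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        # winner mask; ties split the gradient, which keeps backward exact
        # for the summed objective even on plateaus.
        winners = xr == out[:, :, :, None, :, None]
        self._cache = (winners, winners.sum(axis=(3, 5)), x.shape)
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        winners, nwin, (n, c, h, w) = self._cache
        g = (grad_out / nwin)[:, :, :, None, :, None]
        return (winners * g).reshape(n, c, h // 2, 2, w // 2, 2).reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    """(n, c, h, w) -> (n, c) spatial mean."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(grad_out[:, :, None, None], self._shape) / (h * w)


class Dense(Layer):
    """Fully connected layer; ``init_scale`` multiplies the He std (a
    near-zero final projection starts triplet training with all triplets
    active instead of a random far-flung embedding geometry)."""

    def __init__(
        self,
        fin: int,
        fout: int,
        rng: np.random.Generator | None = None,
        init_scale: float = 1.0,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = init_scale * np.sqrt(2.0 / fin)
        self.w = (rng.standard_normal((fout, fin)) * scale).astype(np.float64)
        self.b = np.zeros(fout)
        self.fin, self.fout = fin, fout
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[-1] != self.fin:
            raise ValueError(f"expected input size {self.fin}, got {x.shape[-1]}")
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.grads[0][...] = grad_out.T @ self._x
        self.grads[1][...] = grad_out.sum(axis=0)
        return grad_out @ self.w
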