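"""NumPy building blocks for small 3-D convolutional networks.

Every layer exposes three passes in a functional style so that one layer
object can be applied to several inputs per step (required for the shared
Siamese branch):

``forward(x) -> (y, cache)``
    Computes the output and a cache holding whatever the other passes need.
``backward(gy, cache) -> gx``
    Standard gradient backpropagation; parameter gradients accumulate into
    ``layer.grads`` (call :func:`zero_grads` between steps).
``lrp(R, cache, epsilon) -> R_in``
    Epsilon-rule relevance propagation.  For linear layers the incoming
    relevance is divided by the epsilon-stabilized pre-activation and
    redistributed along the weights, then multiplied by the layer input
    (the "input x modified gradient" formulation).  Max-pooling routes
    relevance winner-take-all to the argmax input (first index on ties);
    ReLU passes relevance through unchanged.

Tensors are ``(N, C, D, H, W)`` float arrays.  Convolutions are
shape-preserving (zero padding ``k // 2``), implemented via
``sliding_window_view`` + matmul; their input gradient reuses the same
machinery as a correlation with the flipped, channel-transposed kernel.
"""

from __future__ import annotations

from typing import Any

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv3d",
    "ReLU",
    "MaxPool3d",
    "GlobalMaxPool",
    "Concat",
    "AbsDiffMerge",
    "Dense",
    "stabilize",
]

DTYPE = np.float32


def stabilize(z: np.ndarray, epsilon: float) -> np.ndarray:
    """z + eps * sign(z), with sign(0) treated as +1 so zeros stay safe."""
    s = np.where(z >= 0, 1.0, -1.0)
    return z + epsilon * s


class Layer:
    """Base class; parameterized layers override ``params``/``grads``."""

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {}

    @property
    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def zero_grads(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0

    def forward(self, x: Any) -> tuple[Any, Any]:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy: Any, cache: Any) -> Any:  # pragma: no cover - interface
        raise NotImplementedError

    def lrp(self, R: Any, cache: Any, epsilon: float) -> Any:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, D, H, W) -> (N*D*H*W, C*k^3) patches with 'same' zero padding."""
    n, c, d, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))  # (N,C,D,H,W,k,k,k)
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * d * h * w, c * k**3)
    return np.ascontiguousarray(np.asarray(cols, dtype=DTYPE))


def _col2im(cols: np.ndarray, shape: tuple[int, ...], k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back onto the grid."""
    n, c, d, h, w = shape
    p = k // 2
    patches = cols.reshape(n, d, h, w, c, k, k, k)
    out = np.zeros((n, c, d + 2 * p, h + 2 * p, w + 2 * p), dtype=DTYPE)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                out[:, :, i : i + d, j : j + h, l : l + w] += patches[
                    :, :, :, :, :, i, j, l
                ].transpose(0, 4, 1, 2, 3)
    return out[:, :, p : p + d, p : p + h, p : p + w]


class Conv3d(Layer):
    """Shape-preserving 3-D convolution (cross-correlation), bias on."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        fan_in = in_channels * kernel**3
        scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU stacks
        self.W = (rng.normal(0.0, scale, size=(out_channels, in_channels, kernel, kernel, kernel))).astype(DTYPE)
        self.b = np.zeros(out_channels, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}

    @property
    def grads(self) -> dict[str, np.ndarray]:
        return {"W": self.gW, "b": self.gb}

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, Any]:
        n, c, d, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        cols = _im2col(x, self.kernel)
        wm = self.W.reshape(self.out_channels, -1)
        z = cols @ wm.T + self.b
        z = z.reshape(n, d, h, w, self.out_channels).transpose(0, 4, 1, 2, 3)
        return z, (x.shape, cols, z)

    def _backward_matmul(self, g: np.ndarray, x_shape: tuple[int, ...]) -> np.ndarray:
        """Map an output-space field back to input space through the weights."""
        n, c, d, h, w = x_shape
        gm = g.transpose(0, 2, 3, 4, 1).reshape(n * d * h * w, self.out_channels)
        gcols = gm @ self.W.reshape(self.out_channels, -1)
        return _col2im(np.asarray(gcols, dtype=DTYPE), x_shape, self.kernel)

    def backward(self, gy: np.ndarray, cache: Any) -> np.ndarray:
        x_shape, cols, _ = cache
        n, c, d, h, w = x_shape
        gm = gy.transpose(0, 2, 3, 4, 1).reshape(n * d * h * w, self.out_channels)
        self.gW += (gm.T @ cols).reshape(self.W.shape)
        self.gb += gm.sum(axis=0)
        return self._backward_matmul(np.asarray(gy, dtype=DTYPE), x_shape)

    def lrp(self, R: np.ndarray, cache: Any, epsilon: float) -> np.ndarray:
        x_shape, cols, z = cache
        n, c, d, h, w = x_shape
        s = R / stabilize(z, epsilon)
        back = self._backward_matmul(np.asarray(s, dtype=DTYPE), x_shape)
        # Reconstruct the layer input from its cached patches (center element).
        k = self.kernel
        p = k // 2
        x = (
            cols.reshape(n, d, h, w, self.in_channels, k, k, k)[..., p, p, p]
            .transpose(0, 4, 1, 2, 3)
        )
        return x * back


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> tuple[np.ndarray, Any]:
        mask = x > 0
        return x * mask, mask

    def backward(self, gy: np.ndarray, cache: Any) -> np.ndarray:
        return gy * cache

    def lrp(self, R: np.ndarray, cache: Any, epsilon: float) -> np.ndarray:
        return R


class MaxPool3d(Layer):
    """Window max pooling; window == stride (default 2), -inf padding for odd axes."""

    def __init__(self, size: int = 2):
        self.size = size

    def _windows(self, x: np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
        n, c, d, h, w = x.shape
        s = self.size
        pd, ph, pw = (-d) % s, (-h) % s, (-w) % s
        xp = np.pad(
            x,
            ((0, 0), (0, 0), (0, pd), (0, ph), (0, pw)),
            constant_values=-np.inf,
        )
        dd, hh, ww = xp.shape[2] // s, xp.shape[3] // s, xp.shape[4] // s
        win = xp.reshape(n, c, dd, s, hh, s, ww, s).transpose(0, 1, 2, 4, 6, 3, 5, 7)
        return win.reshape(n, c, dd, hh, ww, s**3), xp.shape

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, Any]:
        win, padded_shape = self._windows(x)
        arg = np.argmax(win, axis=-1)
        y = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]
        return y, (x.shape, padded_shape, arg)

    def _scatter(self, g: np.ndarray, cache: Any) -> np.ndarray:
        x_shape, padded_shape, arg = cache
        n, c = x_shape[:2]
        s = self.size
        dd, hh, ww = arg.shape[2:]
        win = np.zeros((n, c, dd, hh, ww, s**3), dtype=DTYPE)
        np.put_along_axis(win, arg[..., None], np.asarray(g[..., None], dtype=DTYPE), axis=-1)
        xp = win.reshape(n, c, dd, hh, ww, s, s, s).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        xp = xp.reshape(n, c, dd * s, hh * s, ww * s)
        return xp[:, :, : x_shape[2], : x_shape[3], : x_shape[4]]

    def backward(self, gy: np.ndarray, cache: Any) -> np.ndarray:
        return self._scatter(gy, cache)

    def lrp(self, R: np.ndarray, cache: Any, epsilon: float) -> np.ndarray:
        return self._scatter(R, cache)  # winner-take-all routing


class GlobalMaxPool(Layer):
    """(N, C, D, H, W) -> (N, C) max over space; relevance to the argmax voxel."""

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, Any]:
        n, c = x.shape[:2]
        flat = x.reshape(n, c, -1)
        arg = np.argmax(flat, axis=-1)
        y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        return y, (x.shape, arg)

    def _scatter(self, g: np.ndarray, cache: Any) -> np.ndarray:
        x_shape, arg = cache
        n, c = x_shape[:2]
        flat = np.zeros((n, c, int(np.prod(x_shape[2:]))), dtype=DTYPE)
        np.put_along_axis(flat, arg[..., None], np.asarray(g[..., None], dtype=DTYPE), axis=-1)
        return flat.reshape(x_shape)

    def backward(self, gy: np.ndarray, cache: Any) -> np.ndarray:
        return self._scatter(gy, cache)

    def lrp(self, R: np.ndarray, cache: Any, epsilon: float) -> np.ndarray:
        return self._scatter(R, cache)


class Concat(Layer):
    """Channel concatenation of a list of same-spatial-shape tensors."""

    def forward(self, xs: list[np.ndarray]) -> tuple[np.ndarray, Any]:
        sizes = [x.shape[1] for x in xs]
        return np.concatenate(xs, axis=1), sizes

    def _split(self, g: np.ndarray, sizes: list[int]) -> list[np.ndarray]:
        return list(np.split(g, np.cumsum(sizes)[:-1], axis=1))

    def backward(self, gy: np.ndarray, cache: Any) -> list[np.ndarray]:
        return self._split(gy, cache)

    def lrp(self, R: np.ndarray, cache: Any, epsilon: float) -> list[np.ndarray]:
        return self._split(R, cache)


class AbsDiffMerge(Layer):
    """Elementwise |a - b| merge between the two Siamese branches.

    Backward uses the subgradient (sign(a-b) to branch a, -sign to b; zero
    difference routes zero).  Relevance treats the merge locally as the
    linear map sign(d)*a - sign(d)*b and applies the epsilon rule, which
    conserves relevance and routes zero where the branches agree.
    """

    def forward(self, ab: tuple[np.ndarray, np.ndarray]) -> tuple[np.ndarray, Any]:
        a, b = ab
        d = a - b
        sign = np.sign(d)
        return np.abs(d), (a, b, sign)

    def backward(self, gy: np.ndarray, cache: Any) -> tuple[np.ndarray, np.ndarray]:
        _, _, sign = cache
        return gy * sign, -gy * sign

    def lrp(self, R: np.ndarray, cache: Any, epsilon: float) -> tuple[np.ndarray, np.ndarray]:
        a, b, sign = cache
        z = np.abs(a - b)
        s = R / stabilize(z, epsilon)
        return s * (sign * a), s * (-sign * b)


class Dense(Layer):
    """Fully connected layer y = x W^T + b."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_features)
        self.W = rng.normal(0.0, scale, size=(out_features, in_features)).astype(DTYPE)
        self.b = np.zeros(out_features, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}

    @property
    def grads(self) -> dict[str, np.ndarray]:
        return {"W": self.gW, "b": self.gb}

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, Any]:
        z = x @ self.W.T + self.b
        return z, (x, z)

    def backward(self, gy: np.ndarray, cache: Any) -> np.ndarray:
        x, _ = cache
        self.gW += gy.T @ x
        self.gb += gy.sum(axis=0)
        return np.asarray(gy @ self.W, dtype=DTYPE)

    def lrp(self, R: np.ndarray, cache: Any, epsilon: float) -> np.ndarray:
        x, z = cache
        s = R / stabilize(z, epsilon)
        return x * (s @ self.W)
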