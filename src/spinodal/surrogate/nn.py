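"""Minimal 3D convolutional network engine with periodic (circular) padding.

The two surrogates in this package are small fully convolutional networks
whose defining architectural constraint is *circular padding*: every
convolution wraps toroidally, so the networks inherit the periodic boundary
behavior of the physics they emulate.  Circular padding of a convolution is
mathematically identical to tiling the input periodically and cropping after
convolving, and it makes the network exactly equivariant to circular shifts
(shifts divisible by the total pooling factor when downsampling is present).

Layers implement ``forward(x)`` / ``backward(grad)`` with cached
activations; parameters are plain numpy arrays updated by Adam.  Everything
runs in float32 by default (float64 available for gradient checking).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv3d", "Tanh", "SoftClamp", "AvgPool", "Upsample", "Linear",
           "GlobalAvgPool", "Adam", "mse_loss", "mae_loss"]


def _pad_periodic(x: np.ndarray, p: int) -> np.ndarray:
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)), mode="wrap")


def _pad_reflect(x: np.ndarray, p: int) -> np.ndarray:
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)), mode="reflect")


class Conv3d:
    """3D convolution with circular padding, kernel ``k`` (odd), stride 1.

    ``padding_mode`` is ``"circular"`` (default; full forward/backward) or
    ``"reflect"`` (forward only — provided as an ablation to demonstrate
    that breaking periodicity breaks shift equivariance).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 rng: np.random.Generator | None = None,
                 padding_mode: str = "circular", dtype=np.float32,
                 zero_init: bool = False):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        if padding_mode not in ("circular", "reflect"):
            raise ValueError("padding_mode must be 'circular' or 'reflect'")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.padding_mode = padding_mode
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel**3
        scale = 0.0 if zero_init else np.sqrt(2.0 / fan_in)
        self.weight = (rng.standard_normal(
            (out_channels, in_channels, kernel, kernel, kernel)) * scale
        ).astype(dtype)
        self.bias = np.zeros(out_channels, dtype=dtype)
        self.grad_weight = np.zeros_like(self.weight)
        self.grad_bias = np.zeros_like(self.bias)
        self._cache = None
        self._wh_cache: dict = {}
        self._dirty = True

    # -- plumbing ---------------------------------------------------------
    @property
    def params(self):
        return [(self.weight, self.grad_weight), (self.bias, self.grad_bias)]

    def _offsets(self):
        """Kernel tap offsets -p..p along each axis (correlation layout)."""
        p = self.kernel // 2
        return np.arange(-p, p + 1)

    def _weight_hat(self, shape: tuple[int, int, int]) -> np.ndarray:
        """rfftn of the kernel embedded (wrapped) into the field shape.

        The layer computes a circular *correlation*: tap (u, v, w) of the
        kernel multiplies the input at +(u-p, v-p, w-p), so the embedded
        kernel places tap offsets at negated wrapped positions.
        """
        co, ci = self.out_channels, self.in_channels
        wk = np.zeros((co, ci) + shape, dtype=self.weight.dtype)
        offs = self._offsets()
        for a, da in enumerate(offs):
            for b, db in enumerate(offs):
                for c, dc in enumerate(offs):
                    # accumulate: on grids smaller than the kernel, wrapped
                    # taps land on the same voxel and must add
                    wk[:, :, -da % shape[0], -db % shape[1], -dc % shape[2]] += \
                        self.weight[:, :, a, b, c]
        return np.fft.rfftn(wk, axes=(2, 3, 4))

    def _windows(self, x: np.ndarray) -> np.ndarray:
        p = self.kernel // 2
        xp = _pad_reflect(x, p)
        win = np.lib.stride_tricks.sliding_window_view(
            xp, (self.kernel, self.kernel, self.kernel), axis=(2, 3, 4))
        return win  # (B, Ci, X, Y, Z, k, k, k), a view

    # -- forward/backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.padding_mode == "reflect":
            win = self._windows(x)
            y = np.tensordot(win, self.weight, axes=([1, 5, 6, 7], [1, 2, 3, 4]))
            y = np.moveaxis(y, -1, 1)
            y += self.bias[None, :, None, None, None]
            return np.ascontiguousarray(y)
        shape = x.shape[2:]
        if self._dirty:
            self._wh_cache = {}
            self._dirty = False
        wh = self._wh_cache.get(shape)
        if wh is None:
            wh = self._weight_hat(shape)
            self._wh_cache[shape] = wh
        xh = np.fft.rfftn(x, axes=(2, 3, 4))
        self._cache = (xh, wh, shape)
        y = np.fft.irfftn(np.einsum("bi...,oi...->bo...", xh, wh),
                          s=shape, axes=(2, 3, 4))
        y += self.bias[None, :, None, None, None]
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.padding_mode != "circular":
            raise NotImplementedError(
                "backward pass is implemented for circular padding only")
        xh, wh, shape = self._cache
        gh = np.fft.rfftn(grad, axes=(2, 3, 4))
        # dW: correlation of input with the output gradient, cropped to
        # the kernel taps (same wrapped embedding as _weight_hat)
        dw_full = np.fft.irfftn(np.einsum("bo...,bi...->oi...", gh, np.conj(xh)),
                                s=shape, axes=(2, 3, 4))
        offs = self._offsets()
        for a, da in enumerate(offs):
            for b, db in enumerate(offs):
                for c, dc in enumerate(offs):
                    self.grad_weight[:, :, a, b, c] += dw_full[
                        :, :, -da % shape[0], -db % shape[1], -dc % shape[2]
                    ].astype(self.weight.dtype)
        self.grad_bias += grad.sum(axis=(0, 2, 3, 4)).astype(self.bias.dtype)
        # dx: adjoint correlation = convolution with the conjugate kernel
        dx = np.fft.irfftn(np.einsum("bo...,oi...->bi...", gh, np.conj(wh)),
                           s=shape, axes=(2, 3, 4))
        return dx.astype(grad.dtype)

    def mark_dirty(self) -> None:
        """Invalidate the cached kernel spectrum after a weight update."""
        self._dirty = True


class Tanh:
    """Pointwise tanh."""

    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = np.tanh(x)
        self._cache = y
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        y = self._cache
        return grad * (1.0 - y * y)


class SoftClamp:
    """Exact identity on [-inner, inner], tanh saturation toward ``bound``.

    ``f(x) = x`` inside; outside, ``sign(x) * (inner + w * tanh((|x| -
    inner) / w))`` with ``w = bound - inner``, which is C1 at the joint and
    approaches ``bound`` asymptotically.  Keeps iterative rollouts from
    escaping the physical order-parameter range without distorting it.
    """

    params: list = []

    def __init__(self, bound: float = 1.5, inner: float = 1.1):
        if not 0 < inner < bound:
            raise ValueError("need 0 < inner < bound")
        self.bound = bound
        self.inner = inner

    def forward(self, x: np.ndarray) -> np.ndarray:
        w = self.bound - self.inner
        outside = np.abs(x) > self.inner
        t = np.tanh((np.abs(x) - self.inner) / w, where=outside,
                    out=np.zeros_like(x))
        y = np.where(outside, np.sign(x) * (self.inner + w * t), x)
        self._cache = (outside, t)
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        outside, t = self._cache
        return grad * np.where(outside, 1.0 - t * t, 1.0)


class AvgPool:
    """2x2x2 average pooling (the downsampling step between levels)."""

    params: list = []
    factor = 2

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, nx, ny, nz = x.shape
        f = self.factor
        self._shape = x.shape
        y = x.reshape(b, c, nx // f, f, ny // f, f, nz // f, f).mean(axis=(3, 5, 7))
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        f = self.factor
        g = grad / f**3
        g = np.repeat(np.repeat(np.repeat(g, f, axis=2), f, axis=3), f, axis=4)
        return g


class Upsample:
    """Nearest-neighbor 2x upsampling (the decoder's inverse of AvgPool)."""

    params: list = []
    factor = 2

    def forward(self, x: np.ndarray) -> np.ndarray:
        f = self.factor
        return np.repeat(np.repeat(np.repeat(x, f, axis=2), f, axis=3), f, axis=4)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, c, nx, ny, nz = grad.shape
        f = self.factor
        return grad.reshape(b, c, nx // f, f, ny // f, f, nz // f, f).sum(axis=(3, 5, 7))


class Linear:
    """Dense layer for the property head."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.weight = (rng.standard_normal((out_features, in_features))
                       * np.sqrt(1.0 / in_features)).astype(dtype)
        self.bias = np.zeros(out_features, dtype=dtype)
        self.grad_weight = np.zeros_like(self.weight)
        self.grad_bias = np.zeros_like(self.bias)

    @property
    def params(self):
        return [(self.weight, self.grad_weight), (self.bias, self.grad_bias)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        return x @ self.weight.T + self.bias

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._cache
        self.grad_weight += (grad.T @ x).astype(self.weight.dtype)
        self.grad_bias += grad.sum(axis=0).astype(self.bias.dtype)
        return grad @ self.weight


class GlobalAvgPool:
    """Spatial mean per channel: (B, C, X, Y, Z) -> (B, C)."""

    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, c, nx, ny, nz = self._shape
        g = grad[:, :, None, None, None] / (nx * ny * nz)
        return np.broadcast_to(g, self._shape).copy()


class Adam:
    """Adam optimizer over a list of (param, grad) pairs."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for k, (p, g) in enumerate(self.params):
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0.0


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. the prediction."""
    diff = pred - target
    loss = float(np.mean(diff.astype(np.float64) ** 2))
    grad = (2.0 / diff.size) * diff
    return loss, grad


def mae_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its (sub)gradient w.r.t. the prediction."""
    diff = pred - target
    loss = float(np.mean(np.abs(diff.astype(np.float64))))
    grad = np.sign(diff) / diff.size
    return loss, grad.astype(pred.dtype)
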