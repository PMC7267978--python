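"""Minimal 3D-convolutional neural-network engine in NumPy.

Implements exactly the pieces the decoder needs — 3D convolution (via
windowed views + BLAS matmul), batch normalization, ReLU, fully connected
layers, residual blocks, softmax cross-entropy and Adam — with hand-written
backward passes. Keeping the backward pass explicit is what makes the
guided-backprop visualization rule (gradient passed at a ReLU only where both
the forward input and the incoming gradient are positive) a one-line switch.

Layers follow a ``forward(x, mode)`` / ``backward(grad, guided)`` protocol
with ``mode`` in {"train", "eval"}. Activations are cached on the layer
between the two calls.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

try:  # compiled patch extraction/scatter; NumPy fallback keeps numba optional
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a standard dependency
    _HAVE_NUMBA = False

__all__ = [
    "Param", "Layer", "Conv3d", "BatchNorm3d", "ReLU", "Flatten", "Linear",
    "Sequential", "ResidualBlock", "softmax", "cross_entropy", "Adam",
]

# im2col buffers are chunked along the batch axis to stay under this size
_COL_BUDGET_BYTES = 512 * 1024 ** 2


if _HAVE_NUMBA:

    @_njit(cache=True)
    def _im2col_kernel(xp, cols, Do, Ho, Wo, kd, kh, kw, s0, s1, s2):
        n, C = xp.shape[0], xp.shape[1]
        for i in range(n):
            pos = 0
            for od in range(Do):
                for oh in range(Ho):
                    for ow in range(Wo):
                        col = 0
                        for c in range(C):
                            for a in range(kd):
                                for b in range(kh):
                                    for w in range(kw):
                                        cols[i, pos, col] = xp[
                                            i, c, od * s0 + a, oh * s1 + b, ow * s2 + w
                                        ]
                                        col += 1
                        pos += 1

    @_njit(cache=True)
    def _col2im_kernel(gcols, gxp, Do, Ho, Wo, kd, kh, kw, s0, s1, s2):
        n, C = gxp.shape[0], gxp.shape[1]
        for i in range(n):
            pos = 0
            for od in range(Do):
                for oh in range(Ho):
                    for ow in range(Wo):
                        col = 0
                        for c in range(C):
                            for a in range(kd):
                                for b in range(kh):
                                    for w in range(kw):
                                        gxp[i, c, od * s0 + a, oh * s1 + b, ow * s2 + w] += \
                                            gcols[i, pos, col]
                                        col += 1
                        pos += 1


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def initialize(self, rng: np.random.Generator) -> None:  # pragma: no cover
        pass

    def forward(self, x, mode="train"):  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad, guided=False):  # pragma: no cover
        raise NotImplementedError


def _triple(v):
    return tuple(v) if hasattr(v, "__len__") else (v, v, v)


class Conv3d(Layer):
    """3D convolution over (N, C, D, H, W) with 'same'-style integer padding."""

    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding=0, bias=True, dtype=np.float32):
        self.cin = in_channels
        self.cout = out_channels
        self.kernel = _triple(kernel_size)
        self.stride = _triple(stride)
        self.padding = _triple(padding)
        self.dtype = dtype
        self.W = Param(np.zeros((out_channels, in_channels, *self.kernel), dtype=dtype))
        self.b = Param(np.zeros(out_channels, dtype=dtype)) if bias else None

    def initialize(self, rng):
        fan_in = self.cin * int(np.prod(self.kernel))
        std = np.sqrt(2.0 / fan_in)  # He init for ReLU networks
        self.W.value = (std * rng.standard_normal(self.W.value.shape)).astype(self.dtype)
        if self.b is not None:
            self.b.value = np.zeros(self.cout, dtype=self.dtype)

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def out_shape(self, spatial):
        return tuple(
            (n + 2 * p - k) // s + 1
            for n, k, s, p in zip(spatial, self.kernel, self.stride, self.padding)
        )

    # -- helpers ---------------------------------------------------------
    @property
    def _pointwise(self) -> bool:
        return self.kernel == (1, 1, 1) and self.stride == (1, 1, 1)

    def _pad(self, x):
        p0, p1, p2 = self.padding
        if p0 or p1 or p2:
            return np.pad(x, ((0, 0), (0, 0), (p0, p0), (p1, p1), (p2, p2)))
        return x

    def _im2col(self, x, out_sp):
        """Contiguous (n, n_positions, cin*prod(kernel)) patch matrix."""
        xp = self._pad(x)
        s0, s1, s2 = self.stride
        n = x.shape[0]
        ck = self.cin * int(np.prod(self.kernel))
        if _HAVE_NUMBA:
            cols = np.empty((n, int(np.prod(out_sp)), ck), dtype=xp.dtype)
            _im2col_kernel(np.ascontiguousarray(xp), cols, *out_sp,
                           *self.kernel, s0, s1, s2)
            return cols
        wv = sliding_window_view(xp, self.kernel, axis=(2, 3, 4))
        wv = wv[:, :, ::s0, ::s1, ::s2]  # (n, C, Do, Ho, Wo, kd, kh, kw)
        cols = np.ascontiguousarray(wv.transpose(0, 2, 3, 4, 1, 5, 6, 7))
        return cols.reshape(n, -1, ck)

    def _chunk(self, n, spatial_out):
        per_sample = self.cin * int(np.prod(self.kernel)) * int(np.prod(spatial_out))
        per_sample *= np.dtype(self.dtype).itemsize
        return max(1, min(n, _COL_BUDGET_BYTES // max(per_sample, 1)))

    # -- forward/backward ------------------------------------------------
    def forward(self, x, mode="train"):
        for n, k, s, p in zip(x.shape[2:], self.kernel, self.stride, self.padding):
            if n + 2 * p < k:
                raise ValueError(
                    f"spatial extent {x.shape[2:]} too small for kernel {self.kernel}"
                )
        self.x_shape = x.shape
        n = x.shape[0]
        out_sp = self.out_shape(x.shape[2:])
        wmat = self.W.value.reshape(self.cout, -1)
        if self._pointwise:
            # 1x1x1 stride 1: plain channel mixing, no patch extraction
            self.x = x
            xm = x.reshape(n, self.cin, -1)
            y = np.matmul(wmat[None], xm).reshape(n, self.cout, *out_sp)
        else:
            # cache the contiguous patch matrix; backward reuses it
            self.cols = self._im2col(x, out_sp)
            y = (self.cols.reshape(-1, wmat.shape[1]) @ wmat.T)
            y = y.reshape(n, -1, self.cout).transpose(0, 2, 1)
            y = np.ascontiguousarray(y).reshape(n, self.cout, *out_sp)
        if self.b is not None:
            y += self.b.value[None, :, None, None, None]
        return y

    def backward(self, grad, guided=False):
        n = grad.shape[0]
        out_sp = grad.shape[2:]
        wmat = self.W.value.reshape(self.cout, -1)
        if self._pointwise:
            gy = grad.reshape(n, self.cout, -1)
            xm = self.x.reshape(n, self.cin, -1)
            self.W.grad += np.matmul(gy, xm.transpose(0, 2, 1)).sum(axis=0) \
                .reshape(self.W.value.shape)
            gx = np.matmul(wmat.T[None], gy).reshape(self.x_shape)
        else:
            gy2 = np.ascontiguousarray(grad.transpose(0, 2, 3, 4, 1)) \
                .reshape(-1, self.cout)
            cols2 = self.cols.reshape(-1, wmat.shape[1])
            self.W.grad += (gy2.T @ cols2).reshape(self.W.value.shape)
            gcols = (gy2 @ wmat).reshape(n, -1, wmat.shape[1])
            gx = self._col2im(gcols, out_sp)
            del self.cols
        if self.b is not None:
            self.b.grad += grad.sum(axis=(0, 2, 3, 4))
        return gx

    def _col2im(self, gcols, out_sp):
        """Scatter-add patch gradients (n, positions, cin*K) onto the input."""
        n = gcols.shape[0]
        p0, p1, p2 = self.padding
        s0, s1, s2 = self.stride
        kd, kh, kw = self.kernel
        Do, Ho, Wo = out_sp
        padded_sp = tuple(d + 2 * p for d, p in zip(self.x_shape[2:], self.padding))
        gxp = np.zeros((n, self.cin, *padded_sp), dtype=gcols.dtype)
        if _HAVE_NUMBA:
            _col2im_kernel(np.ascontiguousarray(gcols), gxp, Do, Ho, Wo,
                           kd, kh, kw, s0, s1, s2)
        else:
            # (n, Do, Ho, Wo, C, kd, kh, kw) -> (n, C, Do, Ho, Wo, kd, kh, kw)
            g = gcols.reshape(n, Do, Ho, Wo, self.cin, kd, kh, kw) \
                .transpose(0, 4, 1, 2, 3, 5, 6, 7)
            for a in range(kd):
                for b in range(kh):
                    for c in range(kw):
                        gxp[:, :, a:a + s0 * Do:s0, b:b + s1 * Ho:s1,
                            c:c + s2 * Wo:s2] += g[..., a, b, c]
        sl = (slice(None), slice(None),
              slice(p0, gxp.shape[2] - p0) if p0 else slice(None),
              slice(p1, gxp.shape[3] - p1) if p1 else slice(None),
              slice(p2, gxp.shape[4] - p2) if p2 else slice(None))
        return np.ascontiguousarray(gxp[sl])


class BatchNorm3d(Layer):
    """Per-channel batch normalization with affine scale/shift.

    ``momentum=None`` (default) keeps cumulative averages of the batch
    statistics instead of an exponential moving average — more reliable for
    inference when training runs only a few optimizer steps per epoch.
    """

    def __init__(self, channels, momentum=None, eps=1e-5, dtype=np.float32):
        self.c = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.n_batches = 0

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, mode="train"):
        self.mode = mode
        axes = (0, 2, 3, 4)
        if mode == "train":
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.n_batches += 1
            m = (1.0 / self.n_batches) if self.momentum is None else self.momentum
            self.running_mean += m * (mean - self.running_mean)
            self.running_var += m * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self.inv_std = 1.0 / np.sqrt(var + self.eps)
        self.xhat = (x - mean[None, :, None, None, None]) * \
            self.inv_std[None, :, None, None, None]
        return self.gamma.value[None, :, None, None, None] * self.xhat + \
            self.beta.value[None, :, None, None, None]

    def backward(self, grad, guided=False):
        axes = (0, 2, 3, 4)
        self.gamma.grad += (grad * self.xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g_xhat = grad * self.gamma.value[None, :, None, None, None]
        inv = self.inv_std[None, :, None, None, None]
        if self.mode != "train":
            return g_xhat * inv
        m = grad.shape[0] * grad.shape[2] * grad.shape[3] * grad.shape[4]
        sum_g = g_xhat.sum(axis=axes)[None, :, None, None, None]
        sum_gx = (g_xhat * self.xhat).sum(axis=axes)[None, :, None, None, None]
        return (inv / m) * (m * g_xhat - sum_g - self.xhat * sum_gx)


class ReLU(Layer):
    """Rectifier; under guided backprop the gradient is additionally gated on
    its own positivity, keeping only paths with positive influence."""

    def forward(self, x, mode="train"):
        self.mask = x > 0
        return x * self.mask

    def backward(self, grad, guided=False):
        if guided:
            return grad * (self.mask & (grad > 0))
        return grad * self.mask


class Flatten(Layer):
    def forward(self, x, mode="train"):
        self.shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad, guided=False):
        return grad.reshape(self.shape)


class Linear(Layer):
    def __init__(self, in_features, out_features, dtype=np.float32):
        self.din, self.dout = in_features, out_features
        self.dtype = dtype
        self.W = Param(np.zeros((out_features, in_features), dtype=dtype))
        self.b = Param(np.zeros(out_features, dtype=dtype))

    def initialize(self, rng):
        std = np.sqrt(2.0 / self.din)
        self.W.value = (std * rng.standard_normal((self.dout, self.din))).astype(self.dtype)
        self.b.value = np.zeros(self.dout, dtype=self.dtype)

    def params(self):
        return [self.W, self.b]

    def forward(self, x, mode="train"):
        self.x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, grad, guided=False):
        self.W.grad += grad.T @ self.x
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def initialize(self, rng):
        for l in self.layers:
            l.initialize(rng)

    def forward(self, x, mode="train"):
        for l in self.layers:
            x = l.forward(x, mode)
        return x

    def backward(self, grad, guided=False):
        for l in reversed(self.layers):
            grad = l.backward(grad, guided)
        return grad


class ResidualBlock(Layer):
    """out = ReLU(main(x) + shortcut(x)); identity shortcut when shapes match."""

    def __init__(self, main: Sequential, shortcut: Sequential | None = None):
        self.main = main
        self.shortcut = shortcut
        self.out_relu = ReLU()

    def params(self):
        p = self.main.params()
        if self.shortcut is not None:
            p += self.shortcut.params()
        return p

    def initialize(self, rng):
        self.main.initialize(rng)
        if self.shortcut is not None:
            self.shortcut.initialize(rng)

    def forward(self, x, mode="train"):
        h = self.main.forward(x, mode)
        s = x if self.shortcut is None else self.shortcut.forward(x, mode)
        if h.shape != s.shape:
            raise ValueError(f"residual shapes differ: {h.shape} vs {s.shape}")
        return self.out_relu.forward(h + s, mode)

    def backward(self, grad, guided=False):
        g = self.out_relu.backward(grad, guided)
        gh = self.main.backward(g, guided)
        gs = g if self.shortcut is None else self.shortcut.backward(g, guided)
        return gh + gs


# ---------------------------------------------------------------------------
# loss & optimizer
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = np.finfo(p.dtype).tiny
    loss = -np.log(p[np.arange(n), targets] + eps).mean()
    grad = p.copy()
    grad[np.arange(n), targets] -= 1.0
    return float(loss), grad / n


class Adam:
    """Adam with the standard moment estimates and bias correction."""

    def __init__(self, params: list[Param], lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
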