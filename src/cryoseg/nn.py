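"""Minimal NumPy neural-network core used by the U-Net models.

Layers operate on channels-first batches: ``(N, C, X, Y)`` in 2D or
``(N, C, X, Y, Z)`` in 3D.  Every layer implements ``forward(x, train)`` and
``backward(grad)`` with hand-derived gradients; convolutions are expressed as
a small sum over kernel offsets of BLAS ``tensordot`` calls, which is fast
enough for the patch/slice sizes this package trains at and works unchanged
for 2 and 3 spatial dimensions.  All computation is float32 and fully
deterministic for a fixed seed.
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = [
    "Param",
    "ConvNd",
    "ConvTransposeNd",
    "BatchNorm",
    "ReLU",
    "MaxPool",
    "Sigmoid",
    "Adam",
]


class Param:
    """A trainable array and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class ConvNd:
    """Same-size convolution, kernel 3, stride 1, padding 1, in 2D or 3D."""

    def __init__(self, dims: int, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same-size convolution")
        self.dims = dims
        self.kernel = kernel
        fan_in = in_ch * kernel**dims
        self.weight = Param(_he_init(rng, (out_ch, in_ch) + (kernel,) * dims, fan_in))
        self.bias = Param(np.zeros(out_ch, dtype=np.float32))
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        d, k = self.dims, self.kernel
        pad = k // 2
        spatial = x.shape[2:]
        xp = np.pad(x, [(0, 0), (0, 0)] + [(pad, pad)] * d)
        W = self.weight.value
        out = None
        for off in itertools.product(range(k), repeat=d):
            sl = tuple(slice(o, o + n) for o, n in zip(off, spatial))
            xs = xp[(slice(None), slice(None)) + sl]
            w_off = W[(slice(None), slice(None)) + off]  # (F, C)
            term = np.tensordot(xs, w_off, axes=([1], [1]))  # (N, *sp, F)
            out = term if out is None else out + term
        out += self.bias.value
        self._cache = xp if train else None
        return np.ascontiguousarray(np.moveaxis(out, -1, 1))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        d, k = self.dims, self.kernel
        pad = k // 2
        xp = self._cache
        spatial = grad.shape[2:]
        g = np.moveaxis(grad, 1, -1)  # (N, *sp, F)
        W = self.weight.value
        dxp = np.zeros_like(xp)
        n_axes = list(range(d + 1))  # batch + spatial axes of g
        for off in itertools.product(range(k), repeat=d):
            sl = tuple(slice(o, o + n) for o, n in zip(off, spatial))
            idx = (slice(None), slice(None)) + sl
            xs = xp[idx]
            dwo = np.tensordot(g, xs, axes=(n_axes, [0] + list(range(2, 2 + d))))
            self.weight.grad[(slice(None), slice(None)) + off] += dwo
            dxs = np.tensordot(g, W[(slice(None), slice(None)) + off], axes=([-1], [0]))
            dxp[idx] += np.moveaxis(dxs, -1, 1)
        self.bias.grad += g.sum(axis=tuple(n_axes))
        inner = (slice(None), slice(None)) + tuple(slice(pad, pad + n) for n in spatial)
        return np.ascontiguousarray(dxp[inner])


class ConvTransposeNd:
    """Transposed convolution with kernel 2 and stride 2 (x2 upsampling)."""

    def __init__(self, dims: int, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.dims = dims
        fan_in = in_ch
        self.weight = Param(_he_init(rng, (in_ch, out_ch) + (2,) * dims, fan_in))
        self.bias = Param(np.zeros(out_ch, dtype=np.float32))
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        d = self.dims
        spatial = x.shape[2:]
        out_sp = tuple(2 * n for n in spatial)
        W = self.weight.value
        out_ch = W.shape[1]
        out = np.empty((x.shape[0],) + out_sp + (out_ch,), dtype=np.float32)
        for off in itertools.product(range(2), repeat=d):
            w_off = W[(slice(None), slice(None)) + off]  # (C_in, C_out)
            res = np.tensordot(x, w_off, axes=([1], [0]))  # (N, *sp, C_out)
            out[(slice(None),) + tuple(slice(o, None, 2) for o in off)] = res
        out += self.bias.value
        self._cache = x if train else None
        return np.ascontiguousarray(np.moveaxis(out, -1, 1))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        d = self.dims
        x = self._cache
        g = np.moveaxis(grad, 1, -1)  # (N, *2sp, C_out)
        W = self.weight.value
        dx = None
        n_axes = list(range(d + 1))
        for off in itertools.product(range(2), repeat=d):
            go = g[(slice(None),) + tuple(slice(o, None, 2) for o in off)]
            dwo = np.tensordot(x, go, axes=([0] + list(range(2, 2 + d)), n_axes))
            self.weight.grad[(slice(None), slice(None)) + off] += dwo
            term = np.tensordot(go, W[(slice(None), slice(None)) + off], axes=([-1], [1]))
            dx = term if dx is None else dx + term
        self.bias.grad += g.sum(axis=tuple(n_axes))
        return np.ascontiguousarray(np.moveaxis(dx, -1, 1))


class BatchNorm:
    """Batch normalization over batch and spatial axes, per channel."""

    def __init__(self, n_ch: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_ch, dtype=np.float32))
        self.beta = Param(np.zeros(n_ch, dtype=np.float32))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_ch, dtype=np.float32)
        self.running_var = np.ones(n_ch, dtype=np.float32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def _shape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes = (0,) + tuple(range(2, x.ndim))
        sh = self._shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(sh)) * inv_std.reshape(sh)
        out = self.gamma.value.reshape(sh) * xhat + self.beta.value.reshape(sh)
        if train:
            self._cache = (xhat, inv_std)
        return out.astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        axes = (0,) + tuple(range(2, grad.ndim))
        sh = self._shape(grad)
        m = grad.size / grad.shape[1]
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        dxhat = grad * self.gamma.value.reshape(sh)
        s1 = dxhat.sum(axis=axes).reshape(sh)
        s2 = (dxhat * xhat).sum(axis=axes).reshape(sh)
        dx = (inv_std.reshape(sh) / m) * (m * dxhat - s1 - xhat * s2)
        return dx.astype(np.float32)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool:
    """Max pooling with window and stride 2 on every spatial axis."""

    def __init__(self, dims: int):
        self.dims = dims
        self._cache = None

    def params(self):
        return []

    def _windows(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        d = self.dims
        spatial = x.shape[2:]
        if any(n % 2 for n in spatial):
            raise ValueError(f"spatial shape {spatial} not divisible by 2 for pooling")
        shape = list(x.shape[:2])
        for n in spatial:
            shape += [n // 2, 2]
        v = x.reshape(shape)
        # move the window axes (3, 5, ...) to the end
        win_axes = [3 + 2 * i for i in range(d)]
        keep_axes = [0, 1] + [2 + 2 * i for i in range(d)]
        v = v.transpose(keep_axes + win_axes)
        flat = v.reshape(v.shape[: 2 + d] + (2**d,))
        return flat, x.shape

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        flat, in_shape = self._windows(x)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (arg, in_shape)
        return np.ascontiguousarray(out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        d = self.dims
        arg, in_shape = self._cache
        flat = np.zeros(grad.shape + (2**d,), dtype=np.float32)
        np.put_along_axis(flat, arg[..., None], grad[..., None], axis=-1)
        # invert the transpose/reshape of _windows
        v = flat.reshape(grad.shape + (2,) * d)
        order = [0, 1]
        for i in range(d):
            order += [2 + i, 2 + d + i]
        v = v.transpose(order)
        return np.ascontiguousarray(v.reshape(in_shape))


class Sigmoid:
    """Logistic output with logits clamped to +-8.

    The clamp keeps float32 outputs strictly inside (0, 1) and the sigmoid
    derivative bounded away from zero (~3e-4 at the clamp): without it a
    channel whose logits run away saturates to exactly 0 or 1, its gradient
    underflows and the channel can never recover.  sigmoid(8) = 0.99966, so
    the clamp costs nothing in overlap terms.
    """

    LOGIT_CLAMP = 8.0

    def __init__(self):
        self._out = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.clip(x, -self.LOGIT_CLAMP, self.LOGIT_CLAMP)
        out = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._out = out
        return out.astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = self._out
        return (grad * out * (1.0 - out)).astype(np.float32)


class Adam:
    """Adam optimizer with bias correction; ``lr`` is mutable for schedules."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
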