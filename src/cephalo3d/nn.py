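"""Minimal 3D CNN layer library with reverse-mode gradients, in numpy.

Layers operate on channels-first arrays of shape (C, D, H, W) with an
implicit batch of one (the training loop feeds whole volumes one at a time).
Every layer caches what its backward pass needs; ``forward`` then
``backward`` must be called in matching pairs. float32 throughout.

Provided: strided 3D convolution (im2col + GEMM), group normalization, ReLU,
sigmoid, 2x max pooling, 2x trilinear upsampling, and an AdamW optimizer with
decoupled weight decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Param",
    "Conv3d",
    "GroupNorm",
    "ReLU",
    "Sigmoid",
    "MaxPool2",
    "TrilinearUp2",
    "AdamW",
]


@dataclass
class Param:
    value: np.ndarray
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3d(Layer):
    """3D convolution with 'same'-style padding (pad = kernel // 2).

    Output spatial size per axis is ``floor((n + 2*pad - k) / stride) + 1``;
    with odd kernels this is ``ceil(n / stride)``.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        rng: np.random.Generator | None = None,
    ) -> None:
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.pad = kernel // 2
        fan_in = in_channels * kernel**3
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, fan_in))
        self.weight = Param(w)
        self.bias = Param(np.zeros(out_channels))
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def _out_shape(self, shape: tuple[int, ...]) -> tuple[int, int, int]:
        return tuple(
            (n + 2 * self.pad - self.kernel) // self.stride + 1 for n in shape
        )  # type: ignore[return-value]

    def _im2col(self, xpad: np.ndarray, out_sp: tuple[int, int, int]) -> np.ndarray:
        k, s = self.kernel, self.stride
        c = xpad.shape[0]
        n = int(np.prod(out_sp))
        cols = np.empty((c, k**3, n), dtype=np.float32)
        o = 0
        for a in range(k):
            for b in range(k):
                for d in range(k):
                    sl = xpad[
                        :,
                        a : a + s * out_sp[0] : s,
                        b : b + s * out_sp[1] : s,
                        d : d + s * out_sp[2] : s,
                    ]
                    cols[:, o, :] = sl.reshape(c, n)
                    o += 1
        return cols.reshape(c * k**3, n)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        out_sp = self._out_shape(x.shape[1:])
        p = self.pad
        xpad = np.pad(x, ((0, 0), (p, p), (p, p), (p, p))) if p else x
        cols = self._im2col(xpad, out_sp)
        y = self.weight.value @ cols + self.bias.value[:, None]
        self._cache = (cols, xpad.shape, out_sp)
        return y.reshape((self.out_channels,) + out_sp)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xpad_shape, out_sp = self._cache  # type: ignore[misc]
        self._cache = None
        k, s, p = self.kernel, self.stride, self.pad
        n = int(np.prod(out_sp))
        dy = np.asarray(dout, dtype=np.float32).reshape(self.out_channels, n)
        self.weight.grad += dy @ cols.T
        self.bias.grad += dy.sum(axis=1)
        dcols = (self.weight.value.T @ dy).reshape(self.in_channels, k**3, n)
        dxpad = np.zeros(xpad_shape, dtype=np.float32)
        o = 0
        for a in range(k):
            for b in range(k):
                for d in range(k):
                    dxpad[
                        :,
                        a : a + s * out_sp[0] : s,
                        b : b + s * out_sp[1] : s,
                        d : d + s * out_sp[2] : s,
                    ] += dcols[:, o, :].reshape((self.in_channels,) + out_sp)
                    o += 1
        if p:
            return dxpad[:, p:-p, p:-p, p:-p]
        return dxpad


class GroupNorm(Layer):
    """Group normalization over (channels/groups, spatial), batch independent."""

    def __init__(self, groups: int, channels: int, eps: float = 1e-5) -> None:
        if channels % groups != 0:
            raise ValueError(f"channels {channels} not divisible by groups {groups}")
        self.groups = groups
        self.channels = channels
        self.eps = eps
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        sp = x.shape[1:]
        g = self.groups
        xg = x.reshape(g, -1)
        mean = xg.mean(axis=1, keepdims=True)
        var = xg.var(axis=1, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (xg - mean) * inv_std
        y = xhat.reshape(self.channels, *sp) * self.gamma.value[:, None, None, None]
        y += self.beta.value[:, None, None, None]
        self._cache = (xhat, inv_std, sp)
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, sp = self._cache  # type: ignore[misc]
        self._cache = None
        dout = np.asarray(dout, dtype=np.float32)
        xhat_c = xhat.reshape(self.channels, *sp)
        self.gamma.grad += (dout * xhat_c).sum(axis=(1, 2, 3))
        self.beta.grad += dout.sum(axis=(1, 2, 3))
        dxhat = (dout * self.gamma.value[:, None, None, None]).reshape(self.groups, -1)
        m = dxhat.shape[1]
        dx = inv_std * (
            dxhat
            - dxhat.mean(axis=1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=1, keepdims=True)
        )
        return dx.reshape(self.channels, *sp)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0).astype(np.float32)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        # numerically stable logistic
        out = np.empty_like(x, dtype=np.float32)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return (dout * self._out * (1.0 - self._out)).astype(np.float32)


class MaxPool2(Layer):
    """2x2x2 max pooling, stride 2. Spatial dims must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"max pooling requires even spatial dims, got {(d, h, w)}")
        xr = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        xr = xr.transpose(0, 1, 3, 5, 2, 4, 6).reshape(c, d // 2, h // 2, w // 2, 8)
        self._arg = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return xr.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c, d, h, w = self._in_shape
        flat = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=np.float32)
        np.put_along_axis(flat, self._arg[..., None], dout[..., None].astype(np.float32), axis=-1)
        flat = flat.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
        flat = flat.transpose(0, 1, 4, 2, 5, 3, 6)
        return flat.reshape(c, d, h, w)


def _upsample_matrix(n: int) -> np.ndarray:
    """(2n x n) linear-interpolation matrix; output o samples input (o+0.5)/2-0.5."""
    u = np.zeros((2 * n, n), dtype=np.float32)
    for o in range(2 * n):
        c = (o + 0.5) / 2.0 - 0.5
        i0 = int(np.floor(c))
        t = c - i0
        if i0 < 0:
            u[o, 0] = 1.0
        elif i0 >= n - 1:
            u[o, n - 1] = 1.0
        else:
            u[o, i0] = 1.0 - t
            u[o, i0 + 1] = t
    return u


class TrilinearUp2(Layer):
    """Trilinear upsampling by a factor of 2 along each spatial axis."""

    _mats: dict[int, np.ndarray] = {}

    @classmethod
    def _mat(cls, n: int) -> np.ndarray:
        if n not in cls._mats:
            cls._mats[n] = _upsample_matrix(n)
        return cls._mats[n]

    @staticmethod
    def _apply(x: np.ndarray, mat: np.ndarray, axis: int) -> np.ndarray:
        y = np.tensordot(mat, x, axes=(1, axis))
        return np.moveaxis(y, 0, axis).astype(np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        y = x
        for axis in (1, 2, 3):
            y = self._apply(y, self._mat(self._in_shape[axis]), axis)
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dy = dout
        for axis in (3, 2, 1):
            dy = self._apply(dy, self._mat(self._in_shape[axis]).T, axis)
        return dy.astype(np.float32)


class AdamW:
    """Adam with decoupled weight decay (gamma = lr, lambda = weight_decay)."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 0.001,
        weight_decay: float = 0.01,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            mhat = m / bc1
            vhat = v / bc2
            p.value -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.value)
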