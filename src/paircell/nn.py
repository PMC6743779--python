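"""A compact CNN engine on numpy: layers, backprop, and Adam.

Only the operations the inpainting architecture needs are implemented:
3x3 same-padding convolution (stride 1), batch normalization, ReLU, 2x2 max
pooling, 2x nearest-neighbour upsampling and a sigmoid head.  Data layout is
NHWC throughout, float32.  Convolution runs as one im2col matmul forward and
a 9-offset accumulation backward, which keeps everything inside BLAS.

Gradients of every layer are checked against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np

# working dtype; float32 for speed, switchable to float64 for verification
F32 = np.float32


def set_dtype(dtype) -> None:
    """Set the engine's working dtype (float32 default; float64 is used by
    the finite-difference gradient checks)."""
    global F32
    F32 = np.dtype(dtype).type


class Param:
    __slots__ = ("v", "g", "name")

    def __init__(self, v: np.ndarray, name: str = "") -> None:
        self.v = np.asarray(v, dtype=F32)
        self.g = np.zeros_like(self.v)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero same-padding; weights He-initialized."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str = "") -> None:
        scale = np.sqrt(2.0 / (9 * cin))
        self.w = Param(rng.normal(0.0, scale, size=(9 * cin, cout)), f"{name}.w")
        self.b = Param(np.zeros(cout), f"{name}.b")
        self.cin, self.cout = cin, cout
        self._col: np.ndarray | None = None
        self._xshape: tuple | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        # col[..., k*c:(k+1)*c] = padded x shifted by offset k = 3*dy + dx
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        col = np.empty((n, h, w, 9 * c), dtype=x.dtype)
        for dy in range(3):
            for dx in range(3):
                k = 3 * dy + dx
                col[..., k * c : (k + 1) * c] = xp[:, dy : dy + h, dx : dx + w, :]
        return col.reshape(n * h * w, 9 * c)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        col = self._im2col(x)
        out = col @ self.w.v + self.b.v
        self._col = col if train else None
        self._xshape = (n, h, w, c)
        return out.reshape(n, h, w, self.cout)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        dflat = dout.reshape(n * h * w, self.cout)
        self.w.g += self._col.T @ dflat
        self.b.g += dflat.sum(axis=0)
        dcol = (dflat @ self.w.v.T).reshape(n, h, w, 9 * c)
        dxp = np.zeros((n, h + 2, w + 2, c), dtype=F32)
        for dy in range(3):
            for dx in range(3):
                k = 3 * dy + dx
                dxp[:, dy : dy + h, dx : dx + w, :] += dcol[..., k * c : (k + 1) * c]
        self._col = None
        return dxp[:, 1 : 1 + h, 1 : 1 + w, :]


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W); running stats for eval."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5, name: str = "") -> None:
        self.gamma = Param(np.ones(c), f"{name}.gamma")
        self.beta = Param(np.zeros(c), f"{name}.beta")
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(F32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._cache = (xhat, inv.astype(F32), x.shape)
        return (self.gamma.v * xhat + self.beta.v).astype(F32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        m = shape[0] * shape[1] * shape[2]
        self.gamma.g += (dout * xhat).sum(axis=(0, 1, 2))
        self.beta.g += dout.sum(axis=(0, 1, 2))
        dxhat = dout * self.gamma.v
        dx = (
            inv
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=(0, 1, 2))
                - xhat * (dxhat * xhat).sum(axis=(0, 1, 2))
            )
        )
        self._cache = None
        return dx.astype(F32)


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; even spatial dims required."""

    def __init__(self) -> None:
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        if train:
            # mask of (first) argmax within each 2x2 window
            flat = xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4)
            arg = flat.argmax(axis=-1)
            self._cache = (arg, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        arg, shape = self._cache
        n, h, w, c = shape
        dflat = np.zeros((n, h // 2, w // 2, c, 4), dtype=F32)
        np.put_along_axis(dflat, arg[..., None], dout[..., None], axis=-1)
        dx = (
            dflat.reshape(n, h // 2, w // 2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, h, w, c)
        )
        self._cache = None
        return dx


class Upsample2(Layer):
    """2x nearest-neighbour upsampling."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = dout.shape
        return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4)).astype(F32)


class Sigmoid(Layer):
    def __init__(self) -> None:
        self._out: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))
        out = out.astype(F32)
        if train:
            self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._out * (1.0 - self._out)
        self._out = None
        return dx


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Adam:
    """Adam with bias correction; operates in-place on a parameter list."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.v) for p in params]
        self.v = [np.zeros_like(p.v) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.g
            v *= self.b2
            v += (1 - self.b2) * p.g**2
            p.v -= lr_t * m / (np.sqrt(v) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.g[...] = 0.0


def state_dict(params: list[Param], extras: dict[str, np.ndarray] | None = None) -> dict:
    d = {p.name: p.v for p in params}
    if extras:
        d.update(extras)
    return d
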