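"""Minimal seeded numpy backend for realizing layer graphs.

Tensors are NHWC ``float32``.  Every op implements ``forward`` (caching
what its backward pass needs) and ``backward`` (returning input
gradients); there is no implicit graph — the executor in
:mod:`eunet.model` drives ops in a fixed topological order, which makes
whole training runs bitwise-reproducible for a fixed seed.

Convolutions use 'same' padding (extra padding on the bottom/right for
even kernels) and are computed by tap-wise slicing: for a k×k kernel the
input is gathered into a (N·H·W, k·k·C_in) matrix and multiplied against
the weight matrix, with the transposed products scattered back in the
backward pass.  Dilation spaces the taps by the dilation rate.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Op", "Conv2D", "MaxPool2", "Upsample2", "Concat",
    "BatchNorm", "Activation", "Dropout", "Adam", "SGD",
]

F = np.float32


class Param:
    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value.astype(F)
        self.grad = np.zeros_like(self.value)


class Op:
    """Base op: stateless apart from parameters and the forward cache."""

    def params(self) -> list[Param]:
        return []

    def forward(self, xs: list[np.ndarray], training: bool, rng) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> list[np.ndarray]:
        raise NotImplementedError


def _pad_amount(k: int, dilation: int) -> tuple[int, int]:
    total = dilation * (k - 1)
    return total // 2, total - total // 2


class Conv2D(Op):
    def __init__(self, name: str, c_in: int, c_out: int, kernel: tuple[int, int],
                 dilation: int = 1):
        self.c_in, self.c_out = c_in, c_out
        self.kh, self.kw = kernel
        self.dilation = dilation
        self.W = Param(f"{name}.W", np.zeros((self.kh * self.kw * c_in, c_out)))
        self.b = Param(f"{name}.b", np.zeros(c_out))

    def init(self, rng: np.random.Generator) -> None:
        fan_in = self.kh * self.kw * self.c_in
        std = np.sqrt(2.0 / fan_in)
        self.W.value = rng.normal(0.0, std, self.W.value.shape).astype(F)
        self.b.value = np.zeros(self.c_out, dtype=F)

    def params(self):
        return [self.W, self.b]

    def _taps(self, xp: np.ndarray, H: int, W: int) -> np.ndarray:
        d = self.dilation
        cols = np.empty((xp.shape[0], H, W, self.kh * self.kw, self.c_in), dtype=F)
        t = 0
        for i in range(self.kh):
            for j in range(self.kw):
                cols[:, :, :, t, :] = xp[:, i * d:i * d + H, j * d:j * d + W, :]
                t += 1
        return cols

    def forward(self, xs, training, rng):
        (x,) = xs
        N, H, W, _ = x.shape
        ph = _pad_amount(self.kh, self.dilation)
        pw = _pad_amount(self.kw, self.dilation)
        xp = np.pad(x, ((0, 0), ph, pw, (0, 0)))
        cols = self._taps(xp, H, W).reshape(N * H * W, -1)
        y = cols @ self.W.value + self.b.value
        self._cache = (cols, x.shape, ph, pw)
        return y.reshape(N, H, W, self.c_out)

    def backward(self, dy):
        cols, xshape, ph, pw = self._cache
        N, H, W, _ = xshape
        dyf = dy.reshape(N * H * W, self.c_out)
        self.W.grad += cols.T @ dyf
        self.b.grad += dyf.sum(axis=0)
        dcols = (dyf @ self.W.value.T).reshape(N, H, W, self.kh * self.kw, self.c_in)
        dxp = np.zeros((N, H + ph[0] + ph[1], W + pw[0] + pw[1], self.c_in), dtype=F)
        d, t = self.dilation, 0
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, i * d:i * d + H, j * d:j * d + W, :] += dcols[:, :, :, t, :]
                t += 1
        dx = dxp[:, ph[0]:ph[0] + H, pw[0]:pw[0] + W, :]
        return [dx]


class MaxPool2(Op):
    def __init__(self, factor: int = 2):
        self.f = factor

    def forward(self, xs, training, rng):
        (x,) = xs
        N, H, W, C = x.shape
        f = self.f
        win = x.reshape(N, H // f, f, W // f, f, C).transpose(0, 1, 3, 2, 4, 5)
        win = win.reshape(N, H // f, W // f, f * f, C)
        idx = win.argmax(axis=3)
        y = np.take_along_axis(win, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        self._cache = (idx, x.shape)
        return y

    def backward(self, dy):
        idx, (N, H, W, C) = self._cache
        f = self.f
        dwin = np.zeros((N, H // f, W // f, f * f, C), dtype=F)
        np.put_along_axis(dwin, idx[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        dx = dwin.reshape(N, H // f, W // f, f, f, C).transpose(0, 1, 3, 2, 4, 5)
        return [dx.reshape(N, H, W, C)]


class Upsample2(Op):
    """Nearest-neighbour upsampling by an integer factor."""

    def __init__(self, factor: int = 2):
        self.f = factor

    def forward(self, xs, training, rng):
        (x,) = xs
        self._shape = x.shape
        return x.repeat(self.f, axis=1).repeat(self.f, axis=2)

    def backward(self, dy):
        N, H, W, C = self._shape
        f = self.f
        return [dy.reshape(N, H, f, W, f, C).sum(axis=(2, 4))]


class Concat(Op):
    def forward(self, xs, training, rng):
        self._splits = np.cumsum([x.shape[-1] for x in xs])[:-1]
        return np.concatenate(xs, axis=-1)

    def backward(self, dy):
        return np.split(dy, self._splits, axis=-1)


class BatchNorm(Op):
    """Per-channel batch normalization (statistics over N, H, W).

    Training mode uses batch statistics and updates the running moments;
    inference mode uses the running moments, so the two modes coincide
    only once the running averages have converged.
    """

    def __init__(self, name: str, c: int, momentum: float = 0.9, eps: float = 1e-3):
        self.gamma = Param(f"{name}.gamma", np.ones(c))
        self.beta = Param(f"{name}.beta", np.zeros(c))
        self.running_mean = np.zeros(c, dtype=F)
        self.running_var = np.ones(c, dtype=F)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, xs, training, rng):
        (x,) = xs
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(F)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(F)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * invstd
        self._cache = (xhat, invstd.astype(F), training, x.shape)
        return (self.gamma.value * xhat + self.beta.value).astype(F)

    def backward(self, dy):
        xhat, invstd, training, shape = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += dy.sum(axis=(0, 1, 2))
        g = self.gamma.value
        if not training:
            return [dy * g * invstd]
        n = shape[0] * shape[1] * shape[2]
        dxhat = dy * g
        dx = (dxhat - dxhat.mean(axis=(0, 1, 2))
              - xhat * (dxhat * xhat).mean(axis=(0, 1, 2))) * invstd
        return [dx.astype(F)]


class Activation(Op):
    def __init__(self, fn: str):
        if fn not in ("relu", "sigmoid"):
            raise ValueError(f"unsupported activation {fn!r}")
        self.fn = fn

    def forward(self, xs, training, rng):
        (x,) = xs
        if self.fn == "relu":
            y = np.maximum(x, 0)
            self._cache = x > 0
        else:
            y = 1.0 / (1.0 + np.exp(-x.astype(np.float64)))
            y = y.astype(F)
            self._cache = y
        return y

    def backward(self, dy):
        if self.fn == "relu":
            return [dy * self._cache]
        y = self._cache
        return [dy * y * (1.0 - y)]


class Dropout(Op):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, xs, training, rng):
        (x,) = xs
        if not training:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(F) / F(keep)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return [dy]
        return [dy * self._mask]


class Adam:
    """Adaptive-moment optimizer (the field-default training method)."""

    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(F)


class SGD:
    def __init__(self, params: list[Param], lr: float = 1e-2, momentum: float = 0.9):
        self.params = params
        self.lr, self.mu = lr, momentum
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        for p, v in zip(self.params, self.v):
            v *= self.mu
            v += p.grad
            p.value -= (self.lr * v).astype(F)


OPTIMIZERS = {"adam": Adam, "sgd": SGD}
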