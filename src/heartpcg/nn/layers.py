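from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A learnable array and its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    """Affine map on the trailing axis: (..., d_in) -> (..., d_out)."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, name: str = "dense"):
        scale = np.sqrt(2.0 / d_in)  # He init (ReLU networks)
        self.w = Param(rng.normal(0.0, scale, (d_in, d_out)), f"{name}.w")
        self.b = Param(np.zeros(d_out), f"{name}.b")
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        xf = x.reshape(-1, x.shape[-1])
        dyf = dy.reshape(-1, dy.shape[-1])
        self.w.grad += xf.T @ dyf
        self.b.grad += dyf.sum(axis=0)
        return (dy @ self.w.value.T).reshape(x.shape)


class Conv2d(Layer):
    """2-D convolution on (B, C, H, W) maps, square kernel, zero padding."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int,
        rng: np.random.Generator,
        stride: int = 1,
        pad: int | None = None,
        name: str = "conv",
    ):
        self.k, self.stride = k, stride
        self.pad = (k // 2) if pad is None else pad
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.w = Param(rng.normal(0.0, scale, (c_out, c_in, k, k)), f"{name}.w")
        self.b = Param(np.zeros(c_out), f"{name}.b")
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        B, C, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        Ho = (H + 2 * p - k) // s + 1
        Wo = (W + 2 * p - k) // s + 1
        v = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]  # B,C,Ho,Wo,k,k
        cols = v.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho * Wo, C * k * k)
        self._cols = cols if train else None
        self._xshape = (B, C, H, W)
        wf = self.w.value.reshape(self.w.value.shape[0], -1)  # c_out, C*k*k
        y = cols @ wf.T + self.b.value  # B, Ho*Wo, c_out
        return y.transpose(0, 2, 1).reshape(B, -1, Ho, Wo)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        B, C, H, W = self._xshape
        c_out = dy.shape[1]
        Ho, Wo = dy.shape[2], dy.shape[3]
        dyf = np.ascontiguousarray(
            dy.reshape(B, c_out, Ho * Wo).transpose(0, 2, 1)
        )  # B, Ho*Wo, c_out
        cols = self._cols
        self.w.grad += (
            dyf.reshape(-1, c_out).T @ cols.reshape(-1, cols.shape[-1])
        ).reshape(self.w.value.shape)
        self.b.grad += dyf.sum(axis=(0, 1))
        wf = self.w.value.reshape(c_out, -1)
        dcols = dyf @ wf  # B, Ho*Wo, C*k*k
        d6 = dcols.reshape(B, Ho, Wo, C, k, k).transpose(0, 3, 4, 5, 1, 2)
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += d6[:, :, i, j]
        return dxp[:, :, p : p + H, p : p + W] if p else dxp


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class LayerNorm(Layer):
    """Normalization over the trailing axis with learned scale and shift."""

    def __init__(self, dim: int, name: str = "ln", eps: float = 1e-6):
        self.gamma = Param(np.ones(dim), f"{name}.gamma")
        self.beta = Param(np.zeros(dim), f"{name}.beta")
        self.eps = eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self._xhat * self.gamma.value + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.gamma.grad += (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
        self.beta.grad += dy.sum(axis=tuple(range(dy.ndim - 1)))
        dxhat = dy * self.gamma.value
        return inv * (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        )


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    B = logits.shape[0]
    p = softmax(logits)
    loss = -float(np.mean(np.log(p[np.arange(B), labels] + 1e-300)))
    dlogits = p.copy()
    dlogits[np.arange(B), labels] -= 1.0
    return loss, dlogits / B


class SGDMomentum:
    """Classical momentum: v <- mu*v - lr*g; w <- w + v."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        for p, v in zip(self.params, self._v):
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v
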