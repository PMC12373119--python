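"""Minimal CPU neural-network engine: layers, explicit backprop, Adam.

Everything here is plain numpy in ``float32``.  Convolutions are lowered to
GEMM via im2col (``sliding_window_view``), and the input-gradient of a strided
convolution is expressed as another convolution over the zero-dilated output
gradient, so every heavy operation is a single BLAS matmul.  Layers cache what
their backward pass needs; a forward must precede each backward.

Design notes:

* Batch normalization always uses the statistics of the current batch (no
  running averages).  With batch-one inference this degenerates to instance
  normalization, keeping prediction a deterministic function of the single
  input image.
* All randomness is funnelled through a ``numpy.random.Generator`` supplied at
  construction, so identical seeds give bitwise-identical parameters and, in
  the absence of other nondeterminism, bitwise-identical training runs.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "LeakyReLU",
    "ReLU",
    "Tanh",
    "Sigmoid",
    "UpsampleNearest2x",
    "Sequential",
    "Adam",
    "sigmoid",
]

_F32 = np.float32


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Param:
    """A learnable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=_F32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def parameters(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Return (cols, Ho, Wo): cols is (N·Ho·Wo, C·k·k)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, h, w = x.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # N,C,Ho,Wo,k,k
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * ho * wo, c * k * k
    )
    return cols, ho, wo


class Conv2d(Layer):
    """2-D correlation with square kernel, symmetric zero padding."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        pad: int = 0,
        rng: np.random.Generator | None = None,
        init_std: float = 0.02,
    ):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.stride, self.pad = kernel, stride, pad
        self.W = Param(rng.normal(0.0, init_std, (out_ch, in_ch, kernel, kernel)))
        self.b = Param(np.zeros(out_ch))
        self._cache = None

    def parameters(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=_F32)
        n = x.shape[0]
        cols, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        wmat = self.W.value.reshape(self.out_ch, -1)
        out = cols @ wmat.T + self.b.value
        out = out.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2)
        if train:
            self._cache = (cols, x.shape)
        return np.ascontiguousarray(out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, c, h, w = xshape
        gmat = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(
            -1, self.out_ch
        )
        self.W.grad += (gmat.T @ cols).reshape(self.W.value.shape)
        self.b.grad += gmat.sum(axis=0)

        # input gradient = conv(zero-dilated grad, flipped transposed kernel)
        k, s, p = self.k, self.stride, self.pad
        go = grad
        if s > 1:
            ho, wo = grad.shape[2], grad.shape[3]
            dil = np.zeros((n, self.out_ch, (ho - 1) * s + 1, (wo - 1) * s + 1), _F32)
            dil[:, :, ::s, ::s] = grad
            go = dil
        wflip = self.W.value[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        cols2, ho2, wo2 = _im2col(go, k, 1, k - 1 - p)
        dx = cols2 @ wflip.reshape(self.in_ch, -1).T
        dx = dx.reshape(n, ho2, wo2, self.in_ch).transpose(0, 3, 1, 2)
        # dilation arithmetic can overshoot by (H+2p-k) mod s rows/cols
        return np.ascontiguousarray(dx[:, :, :h, :w])


class BatchNorm2d(Layer):
    """Per-channel normalization over (N, H, W) with learnable affine."""

    def __init__(self, ch: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(ch))
        self.beta = Param(np.zeros(ch))
        self.eps = eps
        self._cache = None

    def parameters(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mean = x.mean(axis=(0, 2, 3), keepdims=True)
        var = x.var(axis=(0, 2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        out = self.gamma.value[None, :, None, None] * xhat + self.beta.value[
            None, :, None, None
        ]
        if train:
            self._cache = (xhat, inv)
        return out.astype(_F32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        axes = (0, 2, 3)
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = grad * self.gamma.value[None, :, None, None]
        m = g.mean(axis=axes, keepdims=True)
        mx = (g * xhat).mean(axis=axes, keepdims=True)
        return ((g - m - xhat * mx) * inv).astype(_F32)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mask = x >= 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, self.slope * grad)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(slope=0.0)


class Tanh(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.tanh(x)
        if train:
            self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * (1.0 - self._out**2)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = sigmoid(x)
        if train:
            self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._out * (1.0 - self._out)


class UpsampleNearest2x(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return np.ascontiguousarray(x.repeat(2, axis=2).repeat(2, axis=3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self) -> list[Param]:
        return [p for lay in self.layers for p in lay.parameters()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for lay in reversed(self.layers):
            grad = lay.backward(grad)
        return grad


class Adam:
    """Adam with the (0.5, 0.999) momentum pairing customary for GANs."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 2e-4,
        betas: tuple[float, float] = (0.5, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1.0 - self.b1) * p.grad
            v[...] = self.b2 * v + (1.0 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
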