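"""Minimal CPU convolutional-network engine.

A deliberately small, dependency-light stack of same-padded 2-D
convolutions with ReLU nonlinearities, manual backpropagation and an Adam
optimizer. It exists so the detector's fully-convolutional map regressor
(and the random-filter GAP descriptor) can train and run on a single CPU
core in seconds-to-minutes; it is not a general deep-learning framework.

Shapes follow the (channels, height, width) convention. All convolutions
are cross-correlations with zero padding of k//2, so outputs keep the
input's spatial size (odd kernel sizes only).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

__all__ = ["Conv2D", "ReLU", "ConvNet", "Adam"]


def _corr_valid(a: np.ndarray, k: np.ndarray) -> np.ndarray:
    # FFT wins for small kernels; for the near-input-sized kernels of the
    # weight gradient a sliding-window contraction is ~2.5x faster
    if k.size * 4 < a.size:
        return signal.correlate(a, k, mode="valid", method="fft")
    win = sliding_window_view(a, k.shape)
    return np.einsum("hwuv,uv->hw", win, k)


class Conv2D:
    """Same-padded convolution, He-initialized, odd kernel size."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        scale = np.sqrt(2.0 / (in_ch * kernel * kernel))
        self.W = rng.normal(0.0, scale, size=(out_ch, in_ch, kernel, kernel))
        self.b = np.zeros(out_ch)
        self._cache: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p)))
        self._cache = xp
        out = np.empty((self.out_ch, x.shape[1], x.shape[2]))
        for o in range(self.out_ch):
            acc = self.b[o]
            for c in range(self.in_ch):
                acc = acc + _corr_valid(xp[c], self.W[o, c])
            out[o] = acc
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp = self._cache
        p = self.kernel // 2
        self.dW = np.empty_like(self.W)
        self.db = grad.sum(axis=(1, 2))
        gp = np.pad(grad, ((0, 0), (p, p), (p, p)))
        dx = np.zeros((self.in_ch, grad.shape[1], grad.shape[2]))
        for o in range(self.out_ch):
            for c in range(self.in_ch):
                self.dW[o, c] = _corr_valid(xp[c], grad[o])
                dx[c] += _corr_valid(gp[o], self.W[o, c][::-1, ::-1])
        return dx

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask

    def params(self):
        return []

    def grads(self):
        return []


class ConvNet:
    """A plain stack of layers with shared forward/backward plumbing."""

    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def state_dict(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params(), state):
            p[...] = s


class Adam:
    """Adam with the standard bias correction; operates in-place."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
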