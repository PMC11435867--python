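"""NumPy layers with explicit forward/backward passes.

Activations use NCHW layout and float32. Each layer caches what its own
backward needs during forward; gradients accumulate into ``Param.grad``.
Convolution is im2col + BLAS sgemm, stride 1 only (all the architecture
needs). Everything is deterministic for a fixed RNG and thread setup.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

BN_EPS = 1e-5


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(xp: np.ndarray, k: int) -> np.ndarray:
    # xp: (N, C, Hp, Wp) -> (N*H'*W', C*k*k), H' = Hp-k+1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    n, c, h, w = win.shape[:4]
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k), (n, h, w, c)


class Conv2d(Layer):
    """k x k convolution (cross-correlation), stride 1, optional zero padding."""

    def __init__(self, in_c: int, out_c: int, k: int, pad: int = 0, bias: bool = False,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_c, self.out_c, self.k, self.pad = in_c, out_c, k, pad
        fan_in = in_c * k * k
        std = np.sqrt(2.0 / fan_in)
        self.W = Param(rng.normal(0.0, std, size=(out_c, fan_in)).astype(np.float32))
        self.b = Param(np.zeros(out_c, dtype=np.float32)) if bias else None

    @property
    def kernel(self) -> np.ndarray:
        """Weights in (out_c, in_c, k, k) layout."""
        return self.W.value.reshape(self.out_c, self.in_c, self.k, self.k)

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=True):
        if x.shape[1] != self.in_c:
            raise ValueError(f"expected {self.in_c} input channels, got {x.shape[1]}")
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        self._xp = xp
        cols, (n, h, w, _) = _im2col(xp, self.k)
        out = cols @ self.W.value.T
        if self.b is not None:
            out += self.b.value
        self._out_shape = (n, h, w)
        return np.ascontiguousarray(out.reshape(n, h, w, self.out_c).transpose(0, 3, 1, 2))

    def backward(self, gout):
        n, h, w = self._out_shape
        g = np.ascontiguousarray(gout.transpose(0, 2, 3, 1)).reshape(-1, self.out_c)
        cols, _ = _im2col(self._xp, self.k)
        self.W.grad += g.T @ cols
        if self.b is not None:
            self.b.grad += g.sum(axis=0)
        dcols = (g @ self.W.value).reshape(n, h, w, self.in_c, self.k, self.k)
        dxp = np.zeros_like(self._xp)
        for ki in range(self.k):
            for kj in range(self.k):
                dxp[:, :, ki : ki + h, kj : kj + w] += dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        p = self.pad
        return dxp[:, :, p : dxp.shape[2] - p, p : dxp.shape[3] - p] if p else dxp


class BatchNorm2d(Layer):
    """Per-channel batch normalization with learnable affine terms."""

    def __init__(self, c: int, momentum: float = 0.1):
        self.c = c
        self.momentum = momentum
        self.gamma = Param(np.ones(c, dtype=np.float32))
        self.beta = Param(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + BN_EPS)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        # dtype follows the input (float32 in training, float64 in numeric checks)
        self._xhat, self._invstd = xhat, np.asarray(invstd)
        self._train = train
        self._m = x.shape[0] * x.shape[2] * x.shape[3]
        return self.gamma.value[None, :, None, None] * self._xhat + self.beta.value[None, :, None, None]

    def backward(self, gout):
        xhat, invstd, m = self._xhat, self._invstd, self._m
        self.gamma.grad += (gout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gout.sum(axis=(0, 2, 3))
        gxhat = gout * self.gamma.value[None, :, None, None]
        if not self._train:
            return gxhat * invstd[None, :, None, None]
        s1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (invstd[None, :, None, None] / m) * (m * gxhat - s1 - xhat * s2)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout):
        return gout * self._mask


class Linear(Layer):
    def __init__(self, in_f: int, out_f: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / in_f)
        self.W = Param(rng.normal(0.0, std, size=(out_f, in_f)).astype(np.float32))
        self.b = Param(np.zeros(out_f, dtype=np.float32)) if bias else None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=True):
        self._x = x
        out = x @ self.W.value.T
        if self.b is not None:
            out += self.b.value
        return out

    def backward(self, gout):
        self.W.grad += gout.T @ self._x
        if self.b is not None:
            self.b.grad += gout.sum(axis=0)
        return gout @ self.W.value


class Sequential(Layer):
    def __init__(self, layers: list):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, gout):
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout


def _sigmoid(x):
    return expit(x)


class SEBlock(Layer):
    """Squeeze-and-excitation channel attention.

    Squeeze: global average pool to one scalar per channel. Excitation: a
    two-layer bottleneck (C -> C/r, ReLU, C/r -> C, sigmoid) producing a
    gate in (0, 1) per channel. Scale: multiply each channel by its gate.
    """

    def __init__(self, c: int, reduction: int, bias: bool = False,
                 rng: np.random.Generator | None = None):
        if c % reduction != 0:
            raise ValueError(f"SE reduction {reduction} must divide the channel count {c}")
        rng = rng or np.random.default_rng(0)
        self.c = c
        self.fc1 = Linear(c, c // reduction, bias=bias, rng=rng)
        self.relu = ReLU()
        self.fc2 = Linear(c // reduction, c, bias=bias, rng=rng)

    def params(self):
        return self.fc1.params() + self.fc2.params()

    def gates(self, x: np.ndarray) -> np.ndarray:
        """Per-(sample, channel) attention weights, all in (0, 1)."""
        z = x.mean(axis=(2, 3))
        return _sigmoid(self.fc2.forward(self.relu.forward(self.fc1.forward(z, False), False), False))

    def forward(self, x, train=True):
        self._x = x
        z = x.mean(axis=(2, 3))
        h = self.relu.forward(self.fc1.forward(z, train), train)
        s = _sigmoid(self.fc2.forward(h, train))
        self._s = s
        return x * s[:, :, None, None]

    def backward(self, gout):
        x, s = self._x, self._s
        hw = x.shape[2] * x.shape[3]
        ds = (gout * x).sum(axis=(2, 3))
        dx = gout * s[:, :, None, None]
        dpre = ds * s * (1.0 - s)
        dz = self.fc1.backward(self.relu.backward(self.fc2.backward(dpre)))
        return dx + dz[:, :, None, None] / hw


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple:
    """Mean cross-entropy over the batch; returns (loss, dlogits, probs)."""
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    probs = e / e.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = float(-np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, (dlogits / n).astype(np.float32), probs
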