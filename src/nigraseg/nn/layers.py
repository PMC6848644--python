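"""Minimal CNN building blocks on numpy with explicit backpropagation.

Only what the segmentation nets need: 2D convolution (im2col + GEMM, stride
support, so stride-2 convolutions replace max pooling), a non-overlapping 2x2
transposed convolution for upsampling, ReLU, softmax cross-entropy with an
optional pixel weight mask, and Adam.  Layers cache their forward inputs, so a
layer instance handles one forward/backward pair at a time.  All gradients are
verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "UpConv2x",
    "ReLU",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


class Param:
    """A trainable tensor with its gradient and Adam state."""

    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray) -> None:
        self.value = value
        self.grad = np.zeros_like(value)
        self.m = np.zeros_like(value)
        self.v = np.zeros_like(value)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, Ho*Wo) patch matrix."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, hp, wp = x.shape
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, (n, c, k, k, ho, wo), (s0, s1, s2, s3, s2 * stride, s3 * stride)
    )
    return view.reshape(n, c * k * k, ho * wo), (ho, wo)


def _col2im(cols: np.ndarray, xshape, k: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of `_im2col`: scatter-add patch columns back onto the input grid."""
    n, c, h, w = xshape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    xp = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    cols = cols.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[
                :, :, i, j
            ]
    if pad:
        return xp[:, :, pad : pad + h, pad : pad + w]
    return xp


class Conv2d:
    """k x k convolution; ``stride=2`` doubles as the downsampling operator."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int = 3,
        stride: int = 1,
        pad: int | None = None,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        self.k, self.stride = k, stride
        self.pad = k // 2 if pad is None else pad
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in))
        self.W = Param(w.astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))
        self._cache = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, (ho, wo) = _im2col(x, self.k, self.stride, self.pad)
        y = np.matmul(self.W.value, cols) + self.b.value[:, None]
        self._cache = (x.shape, cols)
        return y.reshape(x.shape[0], -1, ho, wo)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xshape, cols = self._cache
        n, c_out = dy.shape[:2]
        dyf = dy.reshape(n, c_out, -1)
        self.W.grad += np.matmul(dyf, cols.transpose(0, 2, 1)).sum(axis=0)
        self.b.grad += dyf.sum(axis=(0, 2))
        dcols = np.matmul(self.W.value.T, dyf)
        return _col2im(dcols, xshape, self.k, self.stride, self.pad)


class UpConv2x:
    """2x2 transposed convolution with stride 2 (non-overlapping upsampling)."""

    def __init__(
        self, c_in: int, c_out: int, rng: np.random.Generator | None = None, dtype=np.float32
    ) -> None:
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_in, c_out, 2, 2))
        self.W = Param(w.astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))
        self._x = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        # each input pixel expands into its own 2x2 block: no overlap
        y = np.einsum("ncij,cokl->noikjl", x, self.W.value, optimize=True)
        y = y.reshape(n, -1, 2 * h, 2 * w)
        y += self.b.value[None, :, None, None]
        self._x = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        n, c_out, h2, w2 = dy.shape
        dy6 = dy.reshape(n, c_out, h2 // 2, 2, w2 // 2, 2)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        self.W.grad += np.einsum("ncij,noikjl->cokl", x, dy6, optimize=True)
        return np.einsum("noikjl,cokl->ncij", dy6, self.W.value, optimize=True)


class ReLU:
    params: list[Param] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Adam:
    """Adam with bias correction; one optimizer per network keeps losses disconnected."""

    def __init__(
        self,
        params: list[Param],
        alpha: float = 1e-4,
        beta1: float = 0.5,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.alpha, self.beta1, self.beta2, self.eps = alpha, beta1, beta2, eps
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        scale = self.alpha * np.sqrt(1.0 - b2**self.t) / (1.0 - b1**self.t)
        for p in self.params:
            p.m *= b1
            p.m += (1.0 - b1) * p.grad
            p.v *= b2
            p.v += (1.0 - b2) * p.grad**2
            p.value -= scale * p.m / (np.sqrt(p.v) + self.eps)


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, target: np.ndarray, weight: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Mean per-pixel cross entropy and its gradient w.r.t. the logits.

    ``target`` holds integer class indices of shape (N, H, W); an optional
    ``weight`` of the same shape restricts the mean to a pixel subset (used to
    confine the SNpc net's loss to the midbrain).  Returns (loss, dlogits).
    """
    n, c, h, w = logits.shape
    p = softmax(logits, axis=1)
    if weight is None:
        weight = np.ones((n, h, w), dtype=logits.dtype)
    total = float(weight.sum())
    if total == 0.0:
        return 0.0, np.zeros_like(logits)
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, target[:, None].astype(np.int64), 1.0, axis=1)
    logp = np.log(np.clip(p, 1e-12, None))
    loss = -float((weight[:, None] * onehot * logp).sum()) / total
    dlogits = (p - onehot) * (weight[:, None] / total)
    return loss, dlogits.astype(logits.dtype)
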