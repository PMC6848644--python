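"""A compact U-net: strided-convolution encoder, transposed-convolution decoder.

The architecture follows the encoder/decoder-with-skips pattern, with the two
departures the segmentation cascade requires: downsampling is a 3x3
convolution with stride 2 (replacing max pooling), and upsampling is a 2x2
transposed convolution.  Depth and base channel count are configurable; inputs
must be divisible by ``2**(depth-1)``.
"""

from __future__ import annotations

import numpy as np

from .layers import Adam, Conv2d, Param, ReLU, UpConv2x, softmax

__all__ = ["UNet"]


class UNet:
    def __init__(
        self,
        in_channels: int,
        n_classes: int,
        depth: int = 3,
        base_channels: int = 8,
        seed: int = 0,
        dtype=np.float32,
    ) -> None:
        if depth < 2:
            raise ValueError("depth must be >= 2")
        self.in_channels = in_channels
        self.n_classes = n_classes
        self.depth = depth
        self.base_channels = base_channels
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        ch = [base_channels * 2**d for d in range(depth)]

        def conv(ci, co, **kw):
            return Conv2d(ci, co, rng=rng, dtype=dtype, **kw)

        self.enc: list[list] = []
        self.down: list[Conv2d] = []
        for d in range(depth):
            ci = in_channels if d == 0 else ch[d]
            self.enc.append([conv(ci, ch[d]), ReLU(), conv(ch[d], ch[d]), ReLU()])
            if d < depth - 1:
                self.down.append(conv(ch[d], ch[d + 1], stride=2))
        self.up: list[UpConv2x] = []
        self.dec: list[list] = []
        for d in range(depth - 2, -1, -1):
            self.up.append(UpConv2x(ch[d + 1], ch[d], rng=rng, dtype=dtype))
            self.dec.append([conv(2 * ch[d], ch[d]), ReLU(), conv(ch[d], ch[d]), ReLU()])
        self.head = conv(ch[0], n_classes, k=1, pad=0)

    # -- parameter plumbing -------------------------------------------------
    @property
    def params(self) -> list[Param]:
        out: list[Param] = []
        for block in self.enc + self.dec:
            for layer in block:
                out.extend(layer.params)
        for layer in [*self.down, *self.up, self.head]:
            out.extend(layer.params)
        return out

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params]

    def load_state(self, state: list[np.ndarray]) -> None:
        params = self.params
        if len(state) != len(params):
            raise ValueError("state length mismatch")
        for p, v in zip(params, state):
            if p.value.shape != v.shape:
                raise ValueError("state shape mismatch")
            p.value[...] = v.astype(p.value.dtype)

    def optimizer(self, alpha: float, beta1: float, beta2: float) -> Adam:
        return Adam(self.params, alpha=alpha, beta1=beta1, beta2=beta2)

    # -- forward / backward -------------------------------------------------
    def _check_size(self, h: int, w: int) -> None:
        m = 2 ** (self.depth - 1)
        if h % m or w % m:
            raise ValueError(
                f"input {h}x{w} not divisible by 2**(depth-1) = {m}; pad the input first"
            )

    @staticmethod
    def _run(block, x):
        for layer in block:
            x = layer.forward(x)
        return x

    @staticmethod
    def _run_back(block, dy):
        for layer in reversed(block):
            dy = layer.backward(dy)
        return dy

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits of shape (N, n_classes, H, W)."""
        x = np.ascontiguousarray(x, dtype=self.dtype)
        self._check_size(*x.shape[2:])
        skips = []
        for d in range(self.depth):
            x = self._run(self.enc[d], x)
            if d < self.depth - 1:
                skips.append(x)
                x = self.down[d].forward(x)
        self._skip_channels = []
        for i, d in enumerate(range(self.depth - 2, -1, -1)):
            x = self.up[i].forward(x)
            skip = skips[d]
            self._skip_channels.append(skip.shape[1])
            x = self._run(self.dec[i], np.concatenate([skip, x], axis=1))
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from the loss gradient at the logits."""
        dy = self.head.backward(dlogits.astype(self.dtype))
        dskips: dict[int, np.ndarray] = {}
        for i in range(len(self.dec) - 1, -1, -1):
            d = self.depth - 2 - i
            dcat = self._run_back(self.dec[i], dy)
            cs = self._skip_channels[i]
            dskips[d] = dcat[:, :cs]
            dy = self.up[i].backward(dcat[:, cs:])
        for d in range(self.depth - 1, -1, -1):
            if d < self.depth - 1:
                dy = self.down[d].backward(dy)
                dy = dy + dskips[d]
            dy = self._run_back(self.enc[d], dy)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x), axis=1)
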