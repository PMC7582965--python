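"""Minimal convolutional-network engine for the image restorer.

A small, dependency-free (numpy-only) implementation of exactly what the
restorer needs: 2-D convolutions as im2col matrix products, ReLU, 2x2
average pooling, nearest-neighbour upsampling, skip concatenation, an MSE
loss and an Adam optimizer.  The public interface is (N, 1, H, W); layers
run channels-major (C, N, H, W) internally so every im2col slice copy is
block-contiguous.  All
parameter initialization is driven by an explicit Generator, so training is
reproducible bit-for-bit on a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "UNet", "Adam", "mse_loss"]


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(C, N, H, W) -> (C*k*k, N*H*W) patch matrix (same-size output).

    The channels-major layout makes every slice copy block-contiguous (no
    transposes), which is far cheaper than gathering the overlapping sliding
    windows element-wise.
    """
    c, n, h, w = x.shape
    if k == 1:
        return x.reshape(c, n * h * w)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((c, k * k, n, h, w), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, i * k + j] = xp[:, :, i: i + h, j: j + w]
    return cols.reshape(c * k * k, n * h * w)


class Conv2d:
    """Same-padding 2-D convolution with He-initialized weights.

    im2col patches are flattened so both the forward pass and the gradients
    are single large float32 matrix products.
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in = cin * k * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, cin * k * k)).astype(
            np.float32
        )
        self.b = np.zeros(cout, dtype=np.float32)
        self.k, self.cin, self.cout = k, cin, cout
        self._cols: np.ndarray | None = None
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """x is channels-major (C, N, H, W); output likewise."""
        c, n, h, w = x.shape
        pad = self.k // 2
        # (ckk, n*p) layout so the conv is one BLAS call
        cols = _im2col(x.astype(np.float32, copy=False), self.k, pad)
        if train:
            self._cols = cols
        y = self.w @ cols + self.b[:, None]
        return y.reshape(self.cout, n, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        _, n, h, w = dy.shape
        dy = dy.astype(np.float32, copy=False)
        dy2 = dy.reshape(self.cout, n * h * w)
        self.dw = dy2 @ self._cols.T
        self.db = dy2.sum(axis=1)
        if self.k == 1:
            return (self.w.T @ dy2).reshape(self.cin, n, h, w)
        # data gradient = same-padded correlation of dy with the spatially
        # flipped kernel: one matmul instead of a 9x dcols + scatter-add pass
        kk = self.k * self.k
        wt = (
            self.w.reshape(self.cout, self.cin, kk)[:, :, ::-1]
            .transpose(1, 0, 2)
            .reshape(self.cin, self.cout * kk)
        )
        cols_dy = _im2col(dy, self.k, self.k // 2)
        return (np.ascontiguousarray(wt) @ cols_dy).reshape(self.cin, n, h, w)

    @property
    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


def _avgpool2(x):
    c, n, h, w = x.shape
    return x.reshape(c, n, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def _avgpool2_back(dy):
    return np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) * 0.25


def _upsample2(x):
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def _upsample2_back(dy):
    c, n, h, w = dy.shape
    return dy.reshape(c, n, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class _ConvBlock:
    """Two 3x3 conv + ReLU layers."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.a = Conv2d(cin, cout, 3, rng)
        self.b = Conv2d(cout, cout, 3, rng)
        self._pre_a: np.ndarray | None = None
        self._pre_b: np.ndarray | None = None

    def forward(self, x, train=True):
        ya = self.a.forward(x, train)
        ra = np.maximum(ya, 0.0)
        yb = self.b.forward(ra, train)
        rb = np.maximum(yb, 0.0)
        if train:
            self._pre_a, self._pre_b = ya, yb
        return rb

    def backward(self, dy):
        d = self.b.backward(dy * (self._pre_b > 0))
        return self.a.backward(d * (self._pre_a > 0))

    @property
    def layers(self):
        return [self.a, self.b]


class UNet:
    """Small encoder-decoder regressor with skip connections and a global
    residual.

    ``levels`` scales of two-conv blocks; feature width doubles per scale
    from ``base``.  Input and output are single-channel (N, 1, H, W); H and W
    must be divisible by 2**(levels-1).  The network predicts a correction
    added to its input, so the identity mapping is trivially representable —
    a useful property for a denoiser whose target is a higher-SNR version of
    the input.
    """

    def __init__(self, base: int = 16, levels: int = 2, seed: int = 0):
        if levels < 2:
            raise ValueError("levels must be >= 2")
        rng = np.random.default_rng(seed)
        self.base, self.levels, self.seed = base, levels, seed
        self.enc = []
        cin = 1
        for s in range(levels):
            cout = base * (2**s)
            self.enc.append(_ConvBlock(cin, cout, rng))
            cin = cout
        self.dec = []
        for s in range(levels - 2, -1, -1):
            skip = base * (2**s)
            up = base * (2 ** (s + 1))
            self.dec.append(_ConvBlock(up + skip, skip, rng))
        self.out = Conv2d(base, 1, 1, rng)
        self._cache: dict = {}

    @property
    def layers(self):
        out = []
        for blk in self.enc + self.dec:
            out.extend(blk.layers)
        out.append(self.out)
        return out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        # network runs channels-major internally: (N,1,H,W) <-> (1,N,H,W)
        xc = np.ascontiguousarray(x.transpose(1, 0, 2, 3))
        skips = []
        h = xc
        for s, blk in enumerate(self.enc):
            h = blk.forward(h, train)
            if s < self.levels - 1:
                skips.append(h)
                h = _avgpool2(h)
        for blk, skip in zip(self.dec, reversed(skips)):
            h = np.concatenate([_upsample2(h), skip], axis=0)
            h = blk.forward(h, train)
        y = xc + self.out.forward(h, train)
        return np.ascontiguousarray(y.transpose(1, 0, 2, 3))

    def backward(self, dy: np.ndarray) -> None:
        d = self.out.backward(
            np.ascontiguousarray(dy.transpose(1, 0, 2, 3))
        )
        dskips: dict[int, np.ndarray] = {}
        # decoders backward from shallowest (applied last) to deepest
        for i, blk in enumerate(reversed(self.dec)):
            dcat = blk.backward(d)
            n_up = blk.a.cin - blk.a.cout  # concat = [upsampled | skip]
            du, dskip = dcat[:n_up], dcat[n_up:]
            dskips[i] = dskip  # decoder at depth s=i consumes skip s=i
            d = _upsample2_back(du)
        for s in range(self.levels - 1, -1, -1):
            if s < self.levels - 1:
                d = _avgpool2_back(d) + dskips[s]
            d = self.enc[s].backward(d)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, train=False)

    # --- checkpointing ----------------------------------------------------

    def state_dict(self) -> dict:
        state = {"base": self.base, "levels": self.levels, "seed": self.seed}
        for i, layer in enumerate(self.layers):
            state[f"w{i}"] = layer.w.copy()
            state[f"b{i}"] = layer.b.copy()
        return state

    @classmethod
    def from_state(cls, state: dict) -> "UNet":
        model = cls(base=int(state["base"]), levels=int(state.get("levels", 2)),
                    seed=int(state["seed"]))
        for i, layer in enumerate(model.layers):
            layer.w = np.asarray(state[f"w{i}"])
            layer.b = np.asarray(state[f"b{i}"])
        return model


class Adam:
    def __init__(self, model: UNet, lr: float = 3e-3, betas=(0.9, 0.999), eps=1e-8):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = [np.zeros_like(p) for layer in model.layers for p, _ in layer.params]
        self.v = [np.zeros_like(p) for layer in model.layers for p, _ in layer.params]

    def step(self) -> None:
        self.t += 1
        i = 0
        for layer in self.model.layers:
            for p, g in layer.params:
                self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
                self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
                mhat = self.m[i] / (1 - self.b1**self.t)
                vhat = self.v[i] / (1 - self.b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
                i += 1


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean-square error and its gradient w.r.t. the prediction."""
    diff = pred - target
    return float(np.mean(diff**2)), 2.0 * diff / diff.size
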