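"""Minimal convolutional-network engine for the segmentation model.

Implements exactly the pieces the encoder-decoder needs — 3x3/1x1
convolutions via im2col + GEMM, ReLU, 2x2 max pooling, nearest-neighbor
upsampling, channel concatenation — each with an explicit backward pass,
plus Adam.  Arrays are float32 NHWC throughout: channels-last makes the
im2col patch matrix nine coherent slice copies, so the matrix multiply,
not memory shuffling, dominates.  The engine is deterministic: identical
seeds give identical parameters and training trajectories.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def _pad1(x: np.ndarray) -> np.ndarray:
    return np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))


def _conv3(xp: np.ndarray, w9: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """3x3 convolution of the pre-padded ``xp`` with per-shift matrices.

    ``xp`` is (N, H+2, W+2, C); ``w9`` is (9, C, F).  Each kernel shift is
    one batched matmul over a strided view — no patch matrix is ever
    materialized, so memory traffic stays at one read of x per shift.
    """
    n = xp.shape[0]
    h, w = out_hw
    f = w9.shape[2]
    y = np.zeros((n, h, w, f), dtype=xp.dtype)
    tmp = np.empty_like(y)
    k = 0
    for di in range(3):
        for dj in range(3):
            np.matmul(xp[:, di : di + h, dj : dj + w, :], w9[k], out=tmp)
            y += tmp
            k += 1
    return y


class Conv2D:
    """k x k convolution (k in {1,3}), same padding, via batched GEMMs.

    Weights are stored as (k*k, cin, cout): one GEMM matrix per kernel
    shift, summed over shifts.
    """

    def __init__(self, rng: np.random.Generator, cin: int, cout: int, k: int = 3):
        if k not in (1, 3):
            raise ValueError("kernel size must be 1 or 3")
        self.k, self.cin, self.cout = k, cin, cout
        fan_in = cin * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (k * k, cin, cout)).astype(F32)
        self.b = np.zeros(cout, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, _ = x.shape
        if train:
            self._x = x
        if self.k == 1:
            y = x.reshape(-1, self.cin) @ self.W[0] + self.b
            return y.reshape(n, h, w, self.cout)
        return _conv3(_pad1(x), self.W, (h, w)) + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        n, h, w, c = x.shape
        dy_flat = dy.reshape(-1, self.cout)
        self.db += dy_flat.sum(axis=0)
        if self.k == 1:
            self.dW[0] += x.reshape(-1, c).T @ dy_flat
            return (dy_flat @ self.W[0].T).reshape(n, h, w, c)
        xp = _pad1(x)  # repadded rather than cached: one coherent copy
        k = 0
        for di in range(3):
            for dj in range(3):
                # (N,H,C,W) x (N,H,W,F) batched over (N,H) -> sum to (C,F)
                prod = np.matmul(
                    xp[:, di : di + h, dj : dj + w, :].swapaxes(-1, -2), dy
                )
                self.dW[k] += prod.sum(axis=(0, 1))
                k += 1
        # backward-data is itself a 3x3 conv of dy with the flipped kernel
        wback = np.ascontiguousarray(self.W[::-1].transpose(0, 2, 1))
        return _conv3(_pad1(dy), wback, (h, w))


class ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2:
    """2x2 max pooling; ties route the gradient to the first maximal cell."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        a = x[:, 0::2, 0::2]
        b = x[:, 0::2, 1::2]
        c = x[:, 1::2, 0::2]
        d = x[:, 1::2, 1::2]
        y = np.maximum(np.maximum(a, b), np.maximum(c, d))
        if train:
            ma = a == y
            mb = (b == y) & ~ma
            mc = (c == y) & ~ma & ~mb
            md = ~(ma | mb | mc)
            self._masks = (ma, mb, mc, md)
            self._shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        ma, mb, mc, md = self._masks
        dx = np.zeros(self._shape, dtype=dy.dtype)
        dx[:, 0::2, 0::2] = dy * ma
        dx[:, 0::2, 1::2] = dy * mb
        dx[:, 1::2, 0::2] = dy * mc
        dx[:, 1::2, 1::2] = dy * md
        return dx


class Upsample2:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h2, w2, c = dy.shape
        return dy.reshape(n, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4))


class UNet:
    """Encoder-decoder with skip connections and a per-pixel sigmoid head.

    ``depth`` down/upsampling levels with ``base * 2^i`` channels at level
    i; two 3x3 conv+ReLU blocks per level; nearest-neighbor upsampling and
    skip concatenation on the way up; a 1x1 conv yields one logit per
    pixel.
    """

    def __init__(self, input_size: int, depth: int, base_channels: int, seed: int):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        if input_size % (2**depth) != 0:
            raise ValueError(
                f"input_size {input_size} not divisible by 2^depth = {2**depth}"
            )
        rng = np.random.default_rng(seed)
        self.input_size = input_size
        self.depth = depth
        self.base_channels = base_channels

        chans = [base_channels * 2**i for i in range(depth + 1)]
        self.enc = []
        cin = 3
        for i in range(depth):
            self.enc.append(
                (Conv2D(rng, cin, chans[i]), ReLU(), Conv2D(rng, chans[i], chans[i]), ReLU(), MaxPool2())
            )
            cin = chans[i]
        self.mid = (Conv2D(rng, cin, chans[depth]), ReLU(), Conv2D(rng, chans[depth], chans[depth]), ReLU())
        self.dec = []
        cbelow = chans[depth]
        for i in reversed(range(depth)):
            self.dec.append(
                (Upsample2(), Conv2D(rng, cbelow + chans[i], chans[i]), ReLU(), Conv2D(rng, chans[i], chans[i]), ReLU())
            )
            cbelow = chans[i]
        self.head = Conv2D(rng, chans[0], 1, k=1)

    # -- parameter access -------------------------------------------------
    def conv_layers(self) -> list[Conv2D]:
        layers = []
        for c1, _, c2, _, _ in self.enc:
            layers += [c1, c2]
        layers += [self.mid[0], self.mid[2]]
        for _, c1, _, c2, _ in self.dec:
            layers += [c1, c2]
        layers.append(self.head)
        return layers

    def params(self):
        out = []
        for layer in self.conv_layers():
            out.extend(layer.params())
        return out

    def zero_grad(self) -> None:
        for layer in self.conv_layers():
            layer.dW[:] = 0
            layer.db[:] = 0

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.conv_layers()):
            out[f"conv{i}_W"] = layer.W
            out[f"conv{i}_b"] = layer.b
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.conv_layers()):
            layer.W[:] = state[f"conv{i}_W"]
            layer.b[:] = state[f"conv{i}_b"]

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Return per-pixel logits (N, H, W, 1) for input (N, H, W, 3)."""
        skips = []
        for c1, r1, c2, r2, pool in self.enc:
            x = r1.forward(c1.forward(x, train), train)
            x = r2.forward(c2.forward(x, train), train)
            skips.append(x)
            x = pool.forward(x, train)
        c1, r1, c2, r2 = self.mid
        x = r1.forward(c1.forward(x, train), train)
        x = r2.forward(c2.forward(x, train), train)
        self._skip_channels = []
        for (up, c1, r1, c2, r2), skip in zip(self.dec, reversed(skips)):
            x = up.forward(x, train)
            self._skip_channels.append(skip.shape[-1])
            x = np.concatenate([x, skip], axis=-1)
            x = r1.forward(c1.forward(x, train), train)
            x = r2.forward(c2.forward(x, train), train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.head.backward(dlogits)
        skip_grads = []
        for (up, c1, r1, c2, r2), nskip in zip(reversed(self.dec), reversed(self._skip_channels)):
            d = c1.backward(r1.backward(c2.backward(r2.backward(dx))))
            d_below, d_skip = d[..., :-nskip], d[..., -nskip:]
            skip_grads.append(d_skip)
            dx = up.backward(d_below)
        c1, r1, c2, r2 = self.mid
        dx = c1.backward(r1.backward(c2.backward(r2.backward(dx))))
        for (c1, r1, c2, r2, pool), d_skip in zip(reversed(self.enc), reversed(skip_grads)):
            dx = pool.backward(dx) + d_skip
            dx = c1.backward(r1.backward(c2.backward(r2.backward(dx))))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def dice_bce_loss(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Soft-Dice + binary cross-entropy on logits; returns (loss, dloss/dlogits).

    The combination is the standard choice for heavily imbalanced
    foreground (small objects on large backgrounds): BCE keeps gradients
    well-scaled everywhere while Dice targets overlap directly.
    """
    z = logits.astype(F32)
    y = targets.astype(F32)
    p = sigmoid(z)
    n = z.size
    # stable BCE with logits
    bce = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    dbce = (p - y) / n
    eps = 1.0
    inter = float((p * y).sum())
    denom = float(p.sum() + y.sum()) + eps
    dice = 1.0 - (2.0 * inter + eps) / denom
    ddice_dp = -(2.0 * y * denom - (2.0 * inter + eps)) / denom**2
    ddice = ddice_dp * p * (1.0 - p)
    return bce + dice, (dbce + ddice).astype(F32)


class Adam:
    def __init__(self, net: UNet, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in net.params()]
        self.v = [np.zeros_like(p) for p, _ in net.params()]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for (p, g), m, v in zip(self.net.params(), self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
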