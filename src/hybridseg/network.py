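"""A compact 3D encoder-decoder segmentation network in pure numpy.

The refinement stage needs only a small U-Net (3 resolution levels, base
width 16, instance norm, factor-2 linear upsampling, softmax head), so the
network is implemented directly on numpy arrays with explicit layer-wise
backpropagation: convolutions are evaluated as 27 small GEMMs (one per
kernel offset), which keeps memory flat and maps onto BLAS.  Everything is
float32 and fully deterministic given the seed passed to the initializer —
there are no stochastic kernels.

Tensors are ``(channels, z, y, x)`` for a single example; batching is done
by gradient accumulation in the training loop.  Spatial dimensions must be
divisible by ``2**(levels-1)`` (the inference wrapper pads and crops).

All layers implement ``forward(x)`` / ``backward(grad_out) -> grad_in`` and
expose their parameters and gradients for the Adam optimizer below.  The
backward passes are verified against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["UNet3D", "Adam", "build_network", "softmax", "segmentation_loss"]

_OFFSETS = [(dz, dy, dx) for dz in range(3) for dy in range(3) for dx in range(3)]


class Conv3x3:
    """3³ convolution, stride 1, zero padding 1."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (cin * 27))
        self.w = rng.normal(0.0, std, size=(cout, cin, 27)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._xpad: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        cin, d, h, w = x.shape
        cout = self.w.shape[0]
        xpad = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
        self._xpad = xpad
        n = d * h * w
        y = np.broadcast_to(self.b[:, None], (cout, n)).copy()
        for idx, (dz, dy, dx) in enumerate(_OFFSETS):
            xs = xpad[:, dz : dz + d, dy : dy + h, dx : dx + w].reshape(cin, n)
            y += self.w[:, :, idx] @ xs
        return y.reshape(cout, d, h, w)

    def backward(self, g: np.ndarray) -> np.ndarray:
        cout, d, h, w = g.shape
        cin = self.w.shape[1]
        n = d * h * w
        gf = g.reshape(cout, n)
        xpad = self._xpad
        self.gb += gf.sum(axis=1)
        gx_pad = np.zeros_like(xpad)
        for idx, (dz, dy, dx) in enumerate(_OFFSETS):
            xs = xpad[:, dz : dz + d, dy : dy + h, dx : dx + w].reshape(cin, n)
            self.gw[:, :, idx] += gf @ xs.T
            gx_pad[:, dz : dz + d, dy : dy + h, dx : dx + w] += (
                self.w[:, :, idx].T @ gf
            ).reshape(cin, d, h, w)
        return gx_pad[:, 1:-1, 1:-1, 1:-1]

    def params(self):
        return [("w", self), ("b", self)]


class Conv1x1:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / cin)
        self.w = rng.normal(0.0, std, size=(cout, cin)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._x = None

    def forward(self, x):
        self._x = x
        c, d, h, w = x.shape
        return (self.w @ x.reshape(c, -1) + self.b[:, None]).reshape(-1, d, h, w)

    def backward(self, g):
        c, d, h, w = self._x.shape
        gf = g.reshape(g.shape[0], -1)
        xf = self._x.reshape(c, -1)
        self.gw += gf @ xf.T
        self.gb += gf.sum(axis=1)
        return (self.w.T @ gf).reshape(c, d, h, w)


class InstanceNorm:
    """Per-channel normalization over the spatial axes, learned scale/shift."""

    eps = 1e-5

    def __init__(self, c: int):
        self.w = np.ones(c, dtype=np.float32)  # gamma
        self.b = np.zeros(c, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x):
        c = x.shape[0]
        xf = x.reshape(c, -1)
        mean = xf.mean(axis=1, keepdims=True)
        var = xf.var(axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (xf - mean) * inv
        self._cache = (xhat, inv, x.shape)
        return (self.w[:, None] * xhat + self.b[:, None]).reshape(x.shape)

    def backward(self, g):
        xhat, inv, shape = self._cache
        c = shape[0]
        gf = g.reshape(c, -1)
        n = gf.shape[1]
        self.gw += (gf * xhat).sum(axis=1)
        self.gb += gf.sum(axis=1)
        gxhat = gf * self.w[:, None]
        gx = (
            gxhat
            - gxhat.mean(axis=1, keepdims=True)
            - xhat * (gxhat * xhat).mean(axis=1, keepdims=True)
        ) * inv
        return gx.reshape(shape).astype(np.float32)


class LeakyReLU:
    slope = 0.1

    def __init__(self):
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, g):
        return np.where(self._mask, g, self.slope * g)


class AvgPool2:
    def __init__(self):
        self._shape = None

    def forward(self, x):
        c, d, h, w = x.shape
        self._shape = x.shape
        return x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(2, 4, 6))

    def backward(self, g):
        c, d, h, w = self._shape
        g = g / 8.0
        out = np.repeat(np.repeat(np.repeat(g, 2, axis=1), 2, axis=2), 2, axis=3)
        return out.astype(np.float32)


def _upsample_indices(n: int):
    j = np.arange(2 * n)
    base = j // 2
    nbr = np.where(j % 2 == 0, np.maximum(base - 1, 0), np.minimum(base + 1, n - 1))
    return base, nbr


class LinearUp2:
    """Factor-2 linear upsampling per spatial axis (exact adjoint backward)."""

    def __init__(self):
        self._in_shape = None

    @staticmethod
    def _up_axis(x, axis):
        base, nbr = _upsample_indices(x.shape[axis])
        return 0.75 * np.take(x, base, axis=axis) + 0.25 * np.take(x, nbr, axis=axis)

    @staticmethod
    def _down_adjoint_axis(g, axis, n):
        base, nbr = _upsample_indices(n)
        gm = np.moveaxis(g, axis, 0)
        out = np.zeros((n,) + gm.shape[1:], dtype=np.float32)
        np.add.at(out, base, 0.75 * gm)
        np.add.at(out, nbr, 0.25 * gm)
        return np.moveaxis(out, 0, axis)

    def forward(self, x):
        self._in_shape = x.shape
        for ax in (1, 2, 3):
            x = self._up_axis(x, ax)
        return x.astype(np.float32)

    def backward(self, g):
        for ax in (3, 2, 1):
            g = self._down_adjoint_axis(g, ax, self._in_shape[ax])
        return g.astype(np.float32)


class ConvBlock:
    """Conv3x3 -> InstanceNorm -> LeakyReLU."""

    def __init__(self, cin, cout, rng):
        self.conv = Conv3x3(cin, cout, rng)
        self.norm = InstanceNorm(cout)
        self.act = LeakyReLU()

    def forward(self, x):
        return self.act.forward(self.norm.forward(self.conv.forward(x)))

    def backward(self, g):
        return self.conv.backward(self.norm.backward(self.act.backward(g)))

    def modules(self):
        return [self.conv, self.norm]


class UNet3D:
    """3-level U-Net; input (C, z, y, x) with spatial dims divisible by 4."""

    def __init__(self, in_channels: int, n_classes: int, base_width: int = 16, seed: int = 0):
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        rng = np.random.default_rng(seed)
        w = base_width
        self.in_channels = in_channels
        self.n_classes = n_classes
        self.base_width = w

        self.enc1 = [ConvBlock(in_channels, w, rng), ConvBlock(w, w, rng)]
        self.pool1 = AvgPool2()
        self.enc2 = [ConvBlock(w, 2 * w, rng), ConvBlock(2 * w, 2 * w, rng)]
        self.pool2 = AvgPool2()
        self.bott = [ConvBlock(2 * w, 4 * w, rng), ConvBlock(4 * w, 4 * w, rng)]
        self.up2 = LinearUp2()
        self.dec2 = [ConvBlock(6 * w, 2 * w, rng), ConvBlock(2 * w, 2 * w, rng)]
        self.up1 = LinearUp2()
        self.dec1 = [ConvBlock(3 * w, w, rng), ConvBlock(w, w, rng)]
        self.head = Conv1x1(w, n_classes, rng)
        self._skip_channels = None

    def _blocks(self):
        for blk in self.enc1 + self.enc2 + self.bott + self.dec2 + self.dec1:
            yield from blk.modules()
        yield self.head

    def parameters(self):
        out = []
        for m in self._blocks():
            out.append((m, "w"))
            out.append((m, "b"))
        return out

    @property
    def n_parameters(self) -> int:
        return sum(getattr(m, n).size for m, n in self.parameters())

    def zero_grad(self):
        for m, name in self.parameters():
            getattr(m, "g" + name).fill(0.0)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Returns per-voxel class logits (n_classes, z, y, x)."""
        x = np.asarray(x, dtype=np.float32)
        if x.shape[0] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {x.shape[0]}")
        if any(s % 4 for s in x.shape[1:]):
            raise ValueError(f"spatial dims must be divisible by 4, got {x.shape[1:]}")
        s1 = x
        for blk in self.enc1:
            s1 = blk.forward(s1)
        s2 = self.pool1.forward(s1)
        for blk in self.enc2:
            s2 = blk.forward(s2)
        b = self.pool2.forward(s2)
        for blk in self.bott:
            b = blk.forward(b)
        d2 = np.concatenate([self.up2.forward(b), s2], axis=0)
        for blk in self.dec2:
            d2 = blk.forward(d2)
        d1 = np.concatenate([self.up1.forward(d2), s1], axis=0)
        for blk in self.dec1:
            d1 = blk.forward(d1)
        return self.head.forward(d1)

    def backward(self, g_logits: np.ndarray) -> None:
        g = self.head.backward(g_logits.astype(np.float32))
        for blk in reversed(self.dec1):
            g = blk.backward(g)
        w = self.base_width
        g_up1, g_s1 = g[: 2 * w], g[2 * w :]
        g = self.up1.backward(g_up1)
        for blk in reversed(self.dec2):
            g = blk.backward(g)
        g_up2, g_s2 = g[: 4 * w], g[4 * w :]
        g = self.up2.backward(g_up2)
        for blk in reversed(self.bott):
            g = blk.backward(g)
        g = self.pool2.backward(g) + g_s2
        for blk in reversed(self.enc2):
            g = blk.backward(g)
        g = self.pool1.backward(g) + g_s1
        for blk in reversed(self.enc1):
            g = blk.backward(g)

    # -- (de)serialization ---------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}_{n}": getattr(m, n).copy() for i, (m, n) in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, (m, n) in enumerate(self.parameters()):
            setattr(m, n, state[f"p{i}_{n}"].astype(np.float32).copy())


def build_network(mode: str, n_classes: int, base_width: int = 16, seed: int = 0) -> UNet3D:
    """The refinement network for a pipeline mode.

    ``hybrid`` takes the scan plus one-hot channels for each foreground class
    of the estimated segmentation (1 + (n_classes - 1) input channels);
    ``standard`` takes the scan only.
    """
    if mode not in ("hybrid", "standard"):
        raise ValueError(f"mode must be 'hybrid' or 'standard', got {mode!r}")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    in_ch = 1 if mode == "standard" else 1 + (n_classes - 1)
    return UNet3D(in_ch, n_classes, base_width=base_width, seed=seed)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def segmentation_loss(
    logits: np.ndarray,
    target_onehot: np.ndarray,
    w_dice: float = 0.5,
    w_ce: float = 0.5,
    dice_eps: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Weighted sum of soft-Dice (over foreground classes) and voxel cross-entropy.

    Returns (loss, gradient w.r.t. logits).  The gradient is assembled
    analytically: cross-entropy contributes (p - t) / N and the Dice part is
    chained through the softmax Jacobian.
    """
    p = softmax(logits.astype(np.float64))
    t = target_onehot.astype(np.float64)
    k, n = p.shape[0], p[0].size
    pf = p.reshape(k, n)
    tf = t.reshape(k, n)

    ce = -float((tf * np.log(pf + 1e-12)).sum() / n)
    g_ce = (pf - tf) / n

    # soft Dice over foreground classes
    dl_dp = np.zeros_like(pf)
    dices = []
    for c in range(1, k):
        num = 2.0 * float((pf[c] * tf[c]).sum()) + dice_eps
        den = float(pf[c].sum() + tf[c].sum()) + dice_eps
        dices.append(num / den)
        # d(1 - num/den)/dp = -(2 t den - num) / den²
        dl_dp[c] = -(2.0 * tf[c] * den - num) / (den * den)
    dice_loss = 1.0 - float(np.mean(dices))
    dl_dp /= k - 1

    # chain dice gradient through softmax
    dot = (dl_dp * pf).sum(axis=0, keepdims=True)
    g_dice = pf * (dl_dp - dot)

    loss = w_ce * ce + w_dice * dice_loss
    grad = (w_ce * g_ce + w_dice * g_dice).reshape(logits.shape)
    return loss, grad.astype(np.float32)


class Adam:
    def __init__(self, model: UNet3D, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(m, n)) for m, n in model.parameters()]
        self.v = [np.zeros_like(getattr(m, n)) for m, n in model.parameters()]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (mod, name) in enumerate(self.model.parameters()):
            g = getattr(mod, "g" + name)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p = getattr(mod, name)
            setattr(mod, name, p - self.lr * mhat / (np.sqrt(vhat) + self.eps))
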