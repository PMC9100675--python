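"""Minimal CNN engine in numpy: layers, residual U-Net, Dice loss, Adam.

Implements exactly what the segmenter needs — 2D convolutions (im2col),
batch normalization, PReLU/ReLU, 2×2 max pooling, 2×2 stride-2 transpose
convolutions, skip concatenation — with hand-derived backward passes.
Everything runs in float32 on the CPU; all randomness flows through an
explicit ``numpy.random.Generator``.

Tensors are ``(N, C, H, W)``.  Each layer caches what its backward pass
needs during ``forward(..., train=True)``; ``backward`` returns the gradient
with respect to the layer input and accumulates parameter gradients.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ResUNet", "Adam", "dice_loss", "dice_loss_and_grad"]

_F32 = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(_F32)
        self.grad = np.zeros_like(self.value)


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(_F32)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, OH*OW, C*k*k) patches."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, OH, OW, k, k)
    oh, ow = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * k * k)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int, oh: int, ow: int) -> np.ndarray:
    n, c, h, w = x_shape
    dc = dcols.reshape(n, oh, ow, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=_F32)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += dc[:, :, :, :, i, j]
    if pad:
        return dxp[:, :, pad : pad + h, pad : pad + w]
    return dxp


class Conv2d:
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1, pad: int | None = None, rng=None):
        pad = (k - 1) // 2 if pad is None else pad
        self.k, self.stride, self.pad = k, stride, pad
        self.W = Param(_he(rng, (cin * k * k, cout), cin * k * k))
        self.b = Param(np.zeros(cout, dtype=_F32))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        cols, oh, ow = _im2col(x, self.k, self.stride, self.pad)
        y = cols @ self.W.value + self.b.value
        if train:
            self._cache = (x.shape, cols, oh, ow)
        n = x.shape[0]
        return y.reshape(n, oh, ow, -1).transpose(0, 3, 1, 2)

    def backward(self, dy):
        x_shape, cols, oh, ow = self._cache
        n = dy.shape[0]
        dym = dy.transpose(0, 2, 3, 1).reshape(n, oh * ow, -1)
        self.W.grad += np.tensordot(cols, dym, axes=([0, 1], [0, 1]))
        self.b.grad += dym.sum(axis=(0, 1))
        dcols = dym @ self.W.value.T
        self._cache = None
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad, oh, ow)


class ConvTranspose2x2:
    """Transpose convolution with kernel 2, stride 2 (exact 2x upsampling)."""

    def __init__(self, cin: int, cout: int, rng=None):
        self.W = Param(_he(rng, (cin, cout, 2, 2), cin * 4))
        self.b = Param(np.zeros(cout, dtype=_F32))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        y = np.einsum("ncij,cfab->nfiajb", x, self.W.value, optimize=True)
        y = y.reshape(n, -1, 2 * h, 2 * w) + self.b.value[None, :, None, None]
        if train:
            self._x = x
        return y.astype(_F32)

    def backward(self, dy):
        x = self._x
        n, c, h, w = x.shape
        f = self.W.value.shape[1]
        dyr = dy.reshape(n, f, h, 2, w, 2)
        self.W.grad += np.einsum("ncij,nfiajb->cfab", x, dyr, optimize=True)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        self._x = None
        return np.einsum("nfiajb,cfab->ncij", dyr, self.W.value, optimize=True).astype(_F32)


class BatchNorm2d:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c, dtype=_F32))
        self.beta = Param(np.zeros(c, dtype=_F32))
        self.running_mean = np.zeros(c, dtype=_F32)
        self.running_var = np.ones(c, dtype=_F32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean + self.momentum * mean).astype(_F32)
            self.running_var = ((1 - self.momentum) * self.running_var + self.momentum * var).astype(_F32)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        if train:
            self._cache = (xhat, invstd)
        return (self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]).astype(_F32)

    def backward(self, dy):
        xhat, invstd = self._cache
        self._cache = None
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        dx = (invstd[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)
        return dx.astype(_F32)


class PReLU:
    """Parametric ReLU with one learnable slope per channel (init 0.25)."""

    def __init__(self, c: int):
        self.a = Param(np.full(c, 0.25, dtype=_F32))
        self._x = None

    def params(self):
        return [self.a]

    def forward(self, x, train=False):
        if train:
            self._x = x
        return np.where(x > 0, x, self.a.value[None, :, None, None] * x).astype(_F32)

    def backward(self, dy):
        x = self._x
        self._x = None
        neg = x <= 0
        self.a.grad += (dy * np.where(neg, x, 0)).sum(axis=(0, 2, 3))
        return np.where(neg, self.a.value[None, :, None, None] * dy, dy).astype(_F32)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy):
        mask = self._mask
        self._mask = None
        return dy * mask


class MaxPool2:
    """2×2 max pooling, stride 2; spatial dims must be even."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return y

    def backward(self, dy):
        idx, (n, c, h, w) = self._cache
        self._cache = None
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=_F32)
        np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
        return dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


def _activation(prelu: bool, c: int):
    return PReLU(c) if prelu else ReLU()


class ResidualBlock:
    """conv3x3(s)-BN-act-conv3x3-BN plus (projected) shortcut, then act."""

    def __init__(self, cin, cout, stride, prelu, rng):
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, rng=rng)
        self.bn1 = BatchNorm2d(cout)
        self.act1 = _activation(prelu, cout)
        self.conv2 = Conv2d(cout, cout, 3, rng=rng)
        self.bn2 = BatchNorm2d(cout)
        self.act2 = _activation(prelu, cout)
        if stride != 1 or cin != cout:
            self.proj = Conv2d(cin, cout, 1, stride=stride, pad=0, rng=rng)
            self.proj_bn = BatchNorm2d(cout)
        else:
            self.proj = None

    def params(self):
        ps = self.conv1.params() + self.bn1.params() + self.act1.params()
        ps += self.conv2.params() + self.bn2.params() + self.act2.params()
        if self.proj is not None:
            ps += self.proj.params() + self.proj_bn.params()
        return ps

    def forward(self, x, train=False):
        h = self.act1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        h = self.bn2.forward(self.conv2.forward(h, train), train)
        sc = x if self.proj is None else self.proj_bn.forward(self.proj.forward(x, train), train)
        return self.act2.forward(h + sc, train)

    def backward(self, dy):
        d = self.act2.backward(dy)
        dsc = d
        dh = self.bn2.backward(d)
        dh = self.conv2.backward(dh)
        dh = self.act1.backward(dh)
        dh = self.bn1.backward(dh)
        dx = self.conv1.backward(dh)
        if self.proj is None:
            dx = dx + dsc
        else:
            dx = dx + self.proj.backward(self.proj_bn.backward(dsc))
        return dx


class DecoderStage:
    """Upsample 2×, optionally concat a skip, then two conv3x3+ReLU."""

    def __init__(self, cin, cout, skip_ch, rng):
        self.up = ConvTranspose2x2(cin, cout, rng=rng)
        self.conv1 = Conv2d(cout + skip_ch, cout, 3, rng=rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, rng=rng)
        self.relu2 = ReLU()
        self.skip_ch = skip_ch

    def params(self):
        return self.up.params() + self.conv1.params() + self.conv2.params()

    def forward(self, x, skip, train=False):
        u = self.up.forward(x, train)
        h = u if skip is None else np.concatenate([u, skip], axis=1)
        h = self.relu1.forward(self.conv1.forward(h, train), train)
        return self.relu2.forward(self.conv2.forward(h, train), train)

    def backward(self, dy):
        d = self.conv2.backward(self.relu2.backward(dy))
        d = self.conv1.backward(self.relu1.backward(d))
        if self.skip_ch:
            du, dskip = d[:, : -self.skip_ch], d[:, -self.skip_ch :]
        else:
            du, dskip = d, None
        return self.up.backward(du), dskip


class ResUNet:
    """Residual-encoder U-Net for single-channel 2D segmentation.

    Encoder: 7×7 stride-2 stem + 2×2 max pool, then four residual stages with
    ``blocks`` units each at (f, 2f, 4f, 8f) channels; the 2nd-4th stages halve
    resolution.  Decoder: five transpose-conv upsampling stages with skip
    concatenations from the encoder, 1×1 conv + sigmoid head.  Total
    downsampling 32×, so input sides must be multiples of 32.
    """

    def __init__(self, base_filters=16, blocks=(3, 4, 6, 3), prelu=True, seed=0):
        rng = np.random.default_rng(seed)
        f = base_filters
        self.stem = Conv2d(1, f, 7, stride=2, pad=3, rng=rng)
        self.stem_bn = BatchNorm2d(f)
        self.stem_act = _activation(prelu, f)
        self.pool = MaxPool2()
        chans = [f, 2 * f, 4 * f, 8 * f]
        self.stages: list[list[ResidualBlock]] = []
        cin = f
        for si, (c, n_blocks) in enumerate(zip(chans, blocks)):
            stage = []
            for bi in range(n_blocks):
                stride = 2 if (si > 0 and bi == 0) else 1
                stage.append(ResidualBlock(cin, c, stride, prelu, rng))
                cin = c
            self.stages.append(stage)
        # decoder: from 8f at H/32 back to f at H, skips e3(4f), e2(2f), e1(f), stem(f)
        self.dec = [
            DecoderStage(8 * f, 4 * f, 4 * f, rng),
            DecoderStage(4 * f, 2 * f, 2 * f, rng),
            DecoderStage(2 * f, f, f, rng),
            DecoderStage(f, f, f, rng),
            DecoderStage(f, f, 0, rng),
        ]
        self.head = Conv2d(f, 1, 1, pad=0, rng=rng)
        self._cache = None

    # --- parameter plumbing ---------------------------------------------
    def params(self) -> list[Param]:
        ps = self.stem.params() + self.stem_bn.params() + self.stem_act.params()
        for stage in self.stages:
            for blk in stage:
                ps += blk.params()
        for d in self.dec:
            ps += d.params()
        ps += self.head.params()
        return ps

    def _bn_layers(self):
        out = [self.stem_bn]
        for stage in self.stages:
            for blk in stage:
                out += [blk.bn1, blk.bn2]
                if blk.proj is not None:
                    out.append(blk.proj_bn)
        return out

    def get_state(self) -> list[np.ndarray]:
        state = [p.value.copy() for p in self.params()]
        for bn in self._bn_layers():
            state += [bn.running_mean.copy(), bn.running_var.copy()]
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        ps = self.params()
        for p, v in zip(ps, state[: len(ps)]):
            p.value = v.copy()
        rest = state[len(ps) :]
        for i, bn in enumerate(self._bn_layers()):
            bn.running_mean = rest[2 * i].copy()
            bn.running_var = rest[2 * i + 1].copy()

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0

    # --- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Map (N, 1, H, W) inputs in [0, 1] to probability maps in (0, 1)."""
        x = np.asarray(x, dtype=_F32)
        if x.ndim == 3:
            x = x[:, None]
        h, w = x.shape[2], x.shape[3]
        if h % 32 or w % 32:
            from .errors import ConfigurationError

            raise ConfigurationError(f"input sides must be multiples of 32, got {(h, w)}")
        s1 = self.stem_act.forward(self.stem_bn.forward(self.stem.forward(x, train), train), train)
        e = self.pool.forward(s1, train)
        enc = []
        for stage in self.stages:
            for blk in stage:
                e = blk.forward(e, train)
            enc.append(e)
        e1, e2, e3, e4 = enc
        d = self.dec[0].forward(e4, e3, train)
        d = self.dec[1].forward(d, e2, train)
        d = self.dec[2].forward(d, e1, train)
        d = self.dec[3].forward(d, s1, train)
        d = self.dec[4].forward(d, None, train)
        z = self.head.forward(d, train)
        ez = np.exp(-np.abs(z))  # overflow-safe sigmoid
        p = np.where(z >= 0, 1.0 / (1.0 + ez), ez / (1.0 + ez))
        if train:
            self._cache = p
        return p.astype(_F32)

    def backward(self, dprob: np.ndarray) -> None:
        """Backpropagate gradient of the loss w.r.t. the probability map."""
        p = self._cache
        self._cache = None
        dz = (dprob * p * (1.0 - p)).astype(_F32)
        d = self.head.backward(dz)
        d, _ = self.dec[4].backward(d)
        d, dskip_s1 = self.dec[3].backward(d)
        d, dskip_e1 = self.dec[2].backward(d)
        d, dskip_e2 = self.dec[1].backward(d)
        d, dskip_e3 = self.dec[0].backward(d)
        # walk the encoder backwards, joining each skip gradient where the
        # corresponding stage output branched during the forward pass
        dskips = {2: dskip_e3, 1: dskip_e2, 0: dskip_e1}
        for si in (3, 2, 1, 0):
            for blk in reversed(self.stages[si]):
                d = blk.backward(d)
            if si - 1 in dskips:
                d = d + dskips[si - 1]
        d = self.pool.backward(d)
        if dskip_s1 is not None:
            d = d + dskip_s1
        d = self.stem_act.backward(d)
        d = self.stem_bn.backward(d)
        self.stem.backward(d)


def dice_loss(pred: np.ndarray, truth: np.ndarray, smooth: float = 1.0) -> float:
    """Soft Dice loss 1 − (2Σpt + s)/(Σp + Σt + s), averaged over the batch."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        from .errors import GridError

        raise GridError(f"shapes differ: {pred.shape} vs {truth.shape}")
    axes = tuple(range(1, pred.ndim)) if pred.ndim > 2 else None
    if axes is None:  # single 2D pair
        inter = (pred * truth).sum()
        num = 2 * inter + smooth
        den = pred.sum() + truth.sum() + smooth
        return float(1 - num / den)
    inter = (pred * truth).sum(axis=axes)
    num = 2 * inter + smooth
    den = pred.sum(axis=axes) + truth.sum(axis=axes) + smooth
    return float(np.mean(1 - num / den))


def dice_loss_and_grad(pred: np.ndarray, truth: np.ndarray, smooth: float = 1.0):
    """Batch soft Dice loss and its gradient w.r.t. ``pred``."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    n = pred.shape[0]
    axes = tuple(range(1, pred.ndim))
    inter = (pred * truth).sum(axis=axes)
    sp = pred.sum(axis=axes)
    st = truth.sum(axis=axes)
    num = 2 * inter + smooth
    den = sp + st + smooth
    loss = float(np.mean(1 - num / den))
    shape = (n,) + (1,) * (pred.ndim - 1)
    grad = -(2 * truth * den.reshape(shape) - num.reshape(shape)) / (den.reshape(shape) ** 2)
    return loss, (grad / n).astype(_F32)


class Adam:
    def __init__(self, params: list[Param], lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
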