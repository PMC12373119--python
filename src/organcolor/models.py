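"""Generator, attention module and discriminator for conditional colorization.

The generator is a U-Net conditioned on the CIELAB Lightness plane: an
encoder halves the spatial size at every level down to a 1×1 bottleneck, and
a decoder mirrors it with nearest-neighbour upsampling, each level receiving
the same-resolution encoder features through a skip connection.  The output
head is a tanh, so the two predicted chroma planes (a*, b*) live strictly in
(-1, 1), matching the training normalization.

Attention follows the convolutional block attention module (CBAM): a channel
map ``Mc ∈ R^{C×1×1}`` rescales channels, then a spatial map
``Ms ∈ R^{1×H×W}`` rescales locations,

    F' = Mc(F) ⊗ F,      F'' = Ms(F') ⊗ F',

with ⊗ broadcasting element-wise multiplication.  Channel attention is
``sigmoid(MLP(avgpool F) + MLP(maxpool F))`` with a shared bias-free
two-layer MLP (reduction ratio r); spatial attention is a sigmoid over a 7×7
convolution of the channel-wise [avg; max] planes.  CBAM is applied to every
skip-connection feature map and to the bottleneck (toggleable).

The discriminator is a PatchGAN: a small convolutional stack whose output is
a grid of per-patch real/fake logits (70×70-pixel receptive field; a 256×256
input yields a 30×30 score map).  The image-level score is the arithmetic
mean of the per-patch probabilities.
"""

from __future__ import annotations

import numpy as np

from .nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    Layer,
    LeakyReLU,
    Param,
    ReLU,
    Sequential,
    Sigmoid,
    Tanh,
    UpsampleNearest2x,
    sigmoid,
)

__all__ = ["CBAM", "cbam_refine", "UNetGenerator", "PatchDiscriminator"]

_F32 = np.float32


class CBAM(Layer):
    """Sequential channel-then-spatial attention; geometry-preserving."""

    def __init__(
        self,
        channels: int,
        reduction: int = 16,
        rng: np.random.Generator | None = None,
        init_std: float = 0.02,
    ):
        rng = rng or np.random.default_rng(0)
        hidden = channels // reduction
        if hidden < 1:
            raise ValueError(
                f"channel count {channels} incompatible with reduction {reduction}"
            )
        self.channels, self.reduction = channels, reduction
        self.w0 = Param(rng.normal(0.0, init_std, (hidden, channels)))
        self.w1 = Param(rng.normal(0.0, init_std, (channels, hidden)))
        self.conv = Conv2d(2, 1, 7, stride=1, pad=3, rng=rng, init_std=init_std)
        self._cache = None
        self.mc_: np.ndarray | None = None  # last channel attention, N×C×1×1
        self.ms_: np.ndarray | None = None  # last spatial attention, N×1×H×W

    def parameters(self) -> list[Param]:
        return [self.w0, self.w1] + self.conv.parameters()

    def _mlp(self, v: np.ndarray):
        pre = v @ self.w0.value.T
        h = np.maximum(pre, 0.0)
        return h @ self.w1.value.T, h, pre

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, hh, ww = x.shape
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        flat = x.reshape(n, c, -1)
        avg_c = flat.mean(axis=2)
        amax = flat.argmax(axis=2)
        max_c = np.take_along_axis(flat, amax[:, :, None], axis=2)[:, :, 0]
        za, ha, _ = self._mlp(avg_c)
        zm, hm, _ = self._mlp(max_c)
        mc = sigmoid(za + zm)[:, :, None, None].astype(_F32)
        f1 = x * mc

        avg_s = f1.mean(axis=1, keepdims=True)
        cmax = f1.argmax(axis=1)[:, None]
        max_s = np.take_along_axis(f1, cmax, axis=1)
        cat = np.concatenate([avg_s, max_s], axis=1).astype(_F32)
        zs = self.conv.forward(cat, train)
        ms = sigmoid(zs).astype(_F32)
        out = f1 * ms
        self.mc_, self.ms_ = mc, ms
        if train:
            self._cache = (x, mc, f1, ms, amax, cmax, avg_c, max_c, ha, hm)
        return out

    def refine(self, x: np.ndarray):
        """Apply attention; return ``(F'', Mc, Ms)``."""
        out = self.forward(x, train=False)
        return out, self.mc_, self.ms_

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, mc, f1, ms, amax, cmax, avg_c, max_c, ha, hm = self._cache
        n, c, hh, ww = x.shape

        # spatial branch
        dms = (grad * f1).sum(axis=1, keepdims=True)
        df1 = grad * ms
        dzs = dms * ms * (1.0 - ms)
        dcat = self.conv.backward(dzs.astype(_F32))
        df1 += dcat[:, 0:1] / c
        dmax_s = np.zeros_like(f1)
        np.put_along_axis(dmax_s, cmax, dcat[:, 1:2], axis=1)
        df1 += dmax_s

        # channel branch
        dmc = (df1 * x).sum(axis=(2, 3))
        dx = df1 * mc
        s = mc[:, :, 0, 0]
        dz = dmc * s * (1.0 - s)
        dflat = np.zeros((n, c, hh * ww), dtype=_F32)
        for dv, h, v in ((dz, ha, avg_c), (dz, hm, max_c)):
            dh = dv @ self.w1.value
            self.w1.grad += dv.T @ h
            dpre = dh * (h > 0)
            self.w0.grad += dpre.T @ v
            dvec = dpre @ self.w0.value
            if v is avg_c:
                dflat += dvec[:, :, None] / (hh * ww)
            else:
                scat = np.zeros_like(dflat)
                np.put_along_axis(scat, amax[:, :, None], dvec[:, :, None], axis=2)
                dflat += scat
        dx += dflat.reshape(x.shape)
        return dx.astype(_F32)


def cbam_refine(f: np.ndarray, module: CBAM):
    """Functional wrapper: refine feature map ``f`` → ``(F'', Mc, Ms)``."""
    return module.refine(f)


class _Identity(Layer):
    def forward(self, x, train=True):
        return x

    def backward(self, grad):
        return grad


class UNetGenerator:
    """Encoder–decoder with skip connections mapping L → (a*, b*).

    ``depth = log2(img_size)`` so the bottleneck is 1×1; channel widths grow
    as ``base·min(2^i, 8)``.  Deterministic given its parameters.
    """

    def __init__(
        self,
        img_size: int = 256,
        base: int = 64,
        use_cbam: bool = True,
        cbam_reduction: int = 16,
        in_ch: int = 1,
        out_ch: int = 2,
        rng: np.random.Generator | None = None,
    ):
        if img_size < 8 or img_size & (img_size - 1):
            raise ValueError(f"image size must be a power of two ≥ 8, got {img_size}")
        rng = rng or np.random.default_rng(0)
        self.img_size, self.base = img_size, base
        self.use_cbam, self.cbam_reduction = use_cbam, cbam_reduction
        self.in_ch, self.out_ch = in_ch, out_ch
        depth = int(np.log2(img_size))
        self.depth = depth
        ch = [base * min(2**i, 8) for i in range(depth)]
        self.ch = ch

        self.enc: list[Sequential] = []
        for i in range(depth):
            cin = in_ch if i == 0 else ch[i - 1]
            layers: list[Layer] = [Conv2d(cin, ch[i], 4, 2, 1, rng=rng)]
            if i > 0:
                layers.append(BatchNorm2d(ch[i]))
            layers.append(LeakyReLU(0.2))
            self.enc.append(Sequential(*layers))

        self.att: list[Layer] = [
            CBAM(ch[i], cbam_reduction, rng=rng) if use_cbam else _Identity()
            for i in range(depth)
        ]

        self.dec: list[tuple[UpsampleNearest2x, Sequential]] = []
        prev = ch[depth - 1]
        for i in range(depth - 2, -1, -1):
            block = Sequential(
                Conv2d(prev + ch[i], ch[i], 3, 1, 1, rng=rng),
                BatchNorm2d(ch[i]),
                ReLU(),
            )
            self.dec.append((UpsampleNearest2x(), block))
            prev = ch[i]
        self.head = Sequential(
            UpsampleNearest2x(), Conv2d(ch[0], out_ch, 3, 1, 1, rng=rng), Tanh()
        )

    def parameters(self) -> list[Param]:
        ps: list[Param] = []
        for blk in self.enc:
            ps += blk.parameters()
        for att in self.att:
            ps += att.parameters()
        for _, blk in self.dec:
            ps += blk.parameters()
        ps += self.head.parameters()
        return ps

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.asarray(x, dtype=_F32)
        if x.ndim == 3:
            x = x[:, None]
        n, c, h, w = x.shape
        if h != w or h != self.img_size:
            raise ValueError(
                f"expected square {self.img_size}px input, got {h}×{w}"
            )
        feats = []
        for i, blk in enumerate(self.enc):
            x = blk.forward(x, train)
            feats.append(self.att[i].forward(x, train))
        y = feats[-1]
        for j, (up, blk) in enumerate(self.dec):
            i = self.depth - 2 - j
            y = up.forward(y, train)
            y = np.concatenate([y, feats[i]], axis=1)
            y = blk.forward(y, train)
        return self.head.forward(y, train)

    def backward(self, grad: np.ndarray) -> None:
        g = self.head.backward(grad)
        dfeat: list[np.ndarray | None] = [None] * self.depth
        for j in range(len(self.dec) - 1, -1, -1):
            i = self.depth - 2 - j
            up, blk = self.dec[j]
            g = blk.backward(g)
            nskip = self.ch[i]
            g_up, g_skip = g[:, :-nskip], g[:, -nskip:]
            dfeat[i] = np.ascontiguousarray(g_skip)
            g = up.backward(np.ascontiguousarray(g_up))
        g = self.att[self.depth - 1].backward(g)
        for i in range(self.depth - 2, -1, -1):
            g = self.enc[i + 1].backward(g)
            g = g + self.att[i].backward(dfeat[i])
        self.enc[0].backward(g)

    def __call__(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.forward(x, train)


class PatchDiscriminator:
    """Convolutional patch classifier over L‖a*b* (or a*b* alone).

    Four stride-halving-then-unit conv stages give each output logit a 70×70
    receptive field; ``forward`` returns the logit map, ``scores`` the patch
    probabilities and their per-image arithmetic mean.
    """

    MIN_SIZE = 32

    def __init__(
        self,
        in_ch: int = 3,
        base: int = 64,
        norm: bool = True,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.base = in_ch, base
        b = base
        layers: list[Layer] = [Conv2d(in_ch, b, 4, 2, 1, rng=rng), LeakyReLU(0.2)]
        for cin, cout, stride in ((b, 2 * b, 2), (2 * b, 4 * b, 2), (4 * b, 8 * b, 1)):
            layers.append(Conv2d(cin, cout, 4, stride, 1, rng=rng))
            if norm:
                layers.append(BatchNorm2d(cout))
            layers.append(LeakyReLU(0.2))
        layers.append(Conv2d(8 * b, 1, 4, 1, 1, rng=rng))
        self.net = Sequential(*layers)

    def parameters(self) -> list[Param]:
        return self.net.parameters()

    def _stack(self, cond: np.ndarray | None, ab: np.ndarray) -> np.ndarray:
        ab = np.asarray(ab, dtype=_F32)
        if self.in_ch == ab.shape[1]:
            x = ab
        else:
            if cond is None:
                raise ValueError("discriminator conditioned on L requires cond input")
            cond = np.asarray(cond, dtype=_F32)
            if cond.ndim == 3:
                cond = cond[:, None]
            if cond.shape[2:] != ab.shape[2:]:
                raise ValueError(
                    f"condition {cond.shape[2:]} and chroma {ab.shape[2:]} misaligned"
                )
            x = np.concatenate([cond, ab], axis=1)
        if x.shape[2] < self.MIN_SIZE or x.shape[3] < self.MIN_SIZE:
            raise ValueError(f"input smaller than {self.MIN_SIZE}px minimum")
        return x

    def forward(
        self, cond: np.ndarray | None, ab: np.ndarray, train: bool = True
    ) -> np.ndarray:
        """Return the patch logit map, N×1×h×w."""
        return self.net.forward(self._stack(cond, ab), train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad)

    def scores(self, cond: np.ndarray | None, ab: np.ndarray):
        """Patch probabilities and their arithmetic mean per image."""
        probs = sigmoid(self.forward(cond, ab, train=False))
        return probs, probs.mean(axis=(1, 2, 3))
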