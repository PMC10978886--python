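"""Network architectures for the denoising and blind-SR modules.

All nets operate on NCHW float64 activations with image intensities scaled
to [0, 1].  Each class wires the layers from :mod:`spidesr.nn` and
orchestrates forward/backward explicitly (the graphs contain skips and
two-input layers, so the order is written out rather than inferred).

Desk-scale presets keep the parameter counts small enough for CPU training:
the denoiser is a U-shaped encoder-decoder with 2 down/up levels and a
constant 16 feature channels; the SR network has 4 residual blocks of 24
channels, conditioned on the kernel through spatial-feature-transform (SFT)
layers and finishing with a x4 pixel-shuffle upsampler on top of a bicubic
global skip; the predictor and corrector are 3-conv feature extractors with
dense heads over the flattened 21x21 kernel space.
"""

from __future__ import annotations

import numpy as np

from . import nn

__all__ = ["UNet", "SRNet", "PredictorNet", "CorrectorNet",
           "GaussianKernelDecoder"]


class GaussianKernelDecoder(nn.Module):
    """Differentiable map from a width logit to a legal isotropic kernel.

    The blur-kernel bank is the one-parameter family of isotropic Gaussians,
    so the predictor and corrector regress kernels through this decoder:
    a scalar logit s is squashed to sigma = lo + (hi - lo) * sigmoid(s) and
    rendered as the normalized ``size x size`` Gaussian.  Outputs are
    nonnegative and sum to 1 by construction, and small movements of s give
    small movements of the kernel, which lets the correction loop contract.
    """

    def __init__(self, size: int = 21, sigma_range: tuple[float, float] = (0.2, 4.0)):
        self.size = size
        self.lo, self.hi = sigma_range
        c = (size - 1) / 2.0
        idx = np.arange(size) - c
        self._r2 = (idx[:, None] ** 2 + idx[None, :] ** 2).ravel()  # (size^2,)

    def forward(self, s: np.ndarray) -> np.ndarray:
        """(N, 1) logits -> (N, size^2) flattened kernels."""
        sig01 = 1.0 / (1.0 + np.exp(-s[:, 0]))
        sigma = self.lo + (self.hi - self.lo) * sig01          # (N,)
        g = np.exp(-self._r2[None] / (2.0 * sigma[:, None] ** 2))
        tot = g.sum(axis=1, keepdims=True)
        self._cache = (sig01, sigma, g, tot)
        return g / tot

    def sigma_of(self, s: np.ndarray) -> np.ndarray:
        return self.lo + (self.hi - self.lo) / (1.0 + np.exp(-s[:, 0]))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        sig01, sigma, g, tot = self._cache
        dg_dsig = g * (self._r2[None] / sigma[:, None] ** 3)   # d g / d sigma
        dtot = dg_dsig.sum(axis=1, keepdims=True)
        dk_dsig = (dg_dsig * tot - g * dtot) / tot ** 2
        dsig = (dout * dk_dsig).sum(axis=1)
        ds = dsig * (self.hi - self.lo) * sig01 * (1.0 - sig01)
        return ds[:, None]


class UNet(nn.Module):
    """U-shaped denoiser with skip concatenations and a global residual."""

    def __init__(self, rng: np.random.Generator, in_ch: int = 1,
                 base: int = 16, depth: int = 2):
        self.depth = depth
        c = base
        self.enc = [nn.Conv2d(in_ch if d == 0 else c, c, 3, rng)
                    for d in range(depth)]
        self.enc_act = [nn.ReLU() for _ in range(depth)]
        self.pools = [nn.AvgPool2() for _ in range(depth)]
        self.mid = nn.Conv2d(c, c, 3, rng)
        self.mid_act = nn.ReLU()
        self.ups = [nn.UpsampleNearest2() for _ in range(depth)]
        self.dec = [nn.Conv2d(2 * c, c, 3, rng) for _ in range(depth)]
        self.dec_act = [nn.ReLU() for _ in range(depth)]
        self.out = nn.Conv2d(c, in_ch, 3, rng, init_scale=0.1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        h, skips = x, []
        for conv, act, pool in zip(self.enc, self.enc_act, self.pools):
            h = act.forward(conv.forward(h))
            skips.append(h)
            h = pool.forward(h)
        h = self.mid_act.forward(self.mid.forward(h))
        for up, conv, act, skip in zip(self.ups, self.dec, self.dec_act,
                                       reversed(skips)):
            h = up.forward(h)
            h = act.forward(conv.forward(np.concatenate([h, skip], axis=1)))
        return x + self.out.forward(h)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dh = self.out.backward(dout)
        dskips = []
        for up, conv, act in zip(reversed(self.ups), reversed(self.dec),
                                 reversed(self.dec_act)):
            dcat = conv.backward(act.backward(dh))
            c = dcat.shape[1] // 2
            dh = up.backward(dcat[:, :c])
            dskips.append(dcat[:, c:])
        dh = self.mid.backward(self.mid_act.backward(dh))
        for conv, act, pool, dskip in zip(reversed(self.enc),
                                          reversed(self.enc_act),
                                          reversed(self.pools),
                                          reversed(dskips)):
            dh = conv.backward(act.backward(pool.backward(dh) + dskip))
        return dh + dout  # global residual


class SRNet(nn.Module):
    """Kernel-conditioned x``scale`` SR network over a bicubic global skip.

    The flattened kernel (scaled by its side length so entries are O(1))
    passes through a learned linear reduction to a low-dimensional code;
    the code modulates every residual block through an SFT layer and never
    touches the image as an extra plane.
    """

    def __init__(self, rng: np.random.Generator, scale: int = 4,
                 channels: int = 16, n_blocks: int = 4, code_dim: int = 10,
                 kernel_size: int = 21):
        self.scale = scale
        self.kernel_size = kernel_size
        c = channels
        self.code = nn.Linear(kernel_size * kernel_size, code_dim, rng)
        self.head = nn.Conv2d(1, c, 3, rng)
        self.head_act = nn.ReLU()
        self.blocks = []
        for _ in range(n_blocks):
            self.blocks.append([
                nn.Conv2d(c, c, 3, rng),
                nn.SFT(c, code_dim, rng),
                nn.ReLU(),
                nn.Conv2d(c, c, 3, rng, init_scale=0.1),
            ])
        self.up_conv = nn.Conv2d(c, c * scale * scale, 3, rng)
        self.shuffle = nn.PixelShuffle(scale)
        self.up_act = nn.ReLU()
        self.out = nn.Conv2d(c, 1, 3, rng, init_scale=0.1)

    def forward(self, lr: np.ndarray, k_flat: np.ndarray,
                bicubic_up: np.ndarray) -> np.ndarray:
        """``lr`` (N,1,h,w), ``k_flat`` (N, size^2), ``bicubic_up`` (N,1,H,W)."""
        z = self.code.forward(k_flat * self.kernel_size)
        h = self.head_act.forward(self.head.forward(lr))
        for conv1, sft, act, conv2 in self.blocks:
            b = conv2.forward(act.forward(sft.forward(conv1.forward(h), z)))
            h = h + b
        h = self.up_act.forward(self.shuffle.forward(self.up_conv.forward(h)))
        return bicubic_up + self.out.forward(h)

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dh = self.up_conv.backward(self.shuffle.backward(
            self.up_act.backward(self.out.backward(dout))))
        dz = None
        for conv1, sft, act, conv2 in reversed(self.blocks):
            db = act.backward(conv2.backward(dh))
            df, dzi = sft.backward(db)
            dh = dh + conv1.backward(df)
            dz = dzi if dz is None else dz + dzi
        dlr = self.head.backward(self.head_act.backward(dh))
        dk = self.code.backward(dz) * self.kernel_size
        return dlr, dk


class PredictorNet(nn.Module):
    """LR image -> flattened kernel estimate, via the Gaussian-width decoder."""

    def __init__(self, rng: np.random.Generator, channels: int = 16,
                 kernel_size: int = 21,
                 sigma_range: tuple[float, float] = (0.2, 4.0)):
        c = channels
        self.conv1 = nn.Conv2d(1, c, 3, rng)
        self.act1 = nn.ReLU()
        self.pool = nn.AvgPool2()
        self.conv2 = nn.Conv2d(c, 2 * c, 3, rng)
        self.act2 = nn.ReLU()
        self.conv3 = nn.Conv2d(2 * c, 2 * c, 3, rng)
        self.act3 = nn.ReLU()
        self.gap = nn.GlobalMomentPool()
        self.fc = nn.Linear(4 * c, 1, rng)
        self.decoder = GaussianKernelDecoder(kernel_size, sigma_range)

    def forward(self, lr: np.ndarray) -> np.ndarray:
        h = self.pool.forward(self.act1.forward(self.conv1.forward(lr)))
        h = self.act2.forward(self.conv2.forward(h))
        h = self.act3.forward(self.conv3.forward(h))
        return self.decoder.forward(self.fc.forward(self.gap.forward(h)))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dh = self.gap.backward(self.fc.backward(self.decoder.backward(dout)))
        dh = self.conv3.backward(self.act3.backward(dh))
        dh = self.conv2.backward(self.act2.backward(dh))
        return self.conv1.backward(self.act1.backward(self.pool.backward(dh)))


class CorrectorNet(nn.Module):
    """(SR image, current kernel) -> kernel increment.

    The dense head regresses the *corrected* kernel g(I_SR) through the
    Gaussian-width decoder; the increment is returned as g - k through an
    architectural skip, so the training loss ||K - (C + k)||^2 reduces to
    ||K - g||^2.  The current kernel enters only through that skip and
    through the SR image that was rendered with it, never into the width
    head directly: feeding it back into the head couples the fixed-point
    iteration to itself and can stall convergence, whereas the image-only
    head makes the iteration contract (increments shrink geometrically).
    """

    def __init__(self, rng: np.random.Generator, channels: int = 8,
                 kernel_size: int = 21,
                 sigma_range: tuple[float, float] = (0.2, 4.0)):
        c = channels
        self.ksq = kernel_size * kernel_size
        self.kernel_size = kernel_size
        self.conv1 = nn.Conv2d(1, c, 3, rng)
        self.act1 = nn.ReLU()
        self.pool1 = nn.AvgPool2()
        self.conv2 = nn.Conv2d(c, 2 * c, 3, rng)
        self.act2 = nn.ReLU()
        self.pool2 = nn.AvgPool2()
        self.conv3 = nn.Conv2d(2 * c, 4 * c, 3, rng)
        self.act3 = nn.ReLU()
        self.gap = nn.GlobalMomentPool()
        self.fc1 = nn.Linear(8 * c, 64, rng)
        self.fc_act = nn.ReLU()
        self.fc2 = nn.Linear(64, 1, rng)
        self.decoder = GaussianKernelDecoder(kernel_size, sigma_range)

    def corrected(self, sr: np.ndarray, k_flat: np.ndarray = None) -> np.ndarray:
        """The head's corrected-kernel regression g(I_SR)."""
        h = self.pool1.forward(self.act1.forward(self.conv1.forward(sr)))
        h = self.pool2.forward(self.act2.forward(self.conv2.forward(h)))
        h = self.act3.forward(self.conv3.forward(h))
        f = self.gap.forward(h)
        h = self.fc_act.forward(self.fc1.forward(f))
        return self.decoder.forward(self.fc2.forward(h))

    def forward(self, sr: np.ndarray, k_flat: np.ndarray) -> np.ndarray:
        return self.corrected(sr) - k_flat

    def backward(self, dout: np.ndarray) -> np.ndarray:
        """Backward through :meth:`corrected` (dout w.r.t. the head output)."""
        df = self.fc1.backward(self.fc_act.backward(
            self.fc2.backward(self.decoder.backward(dout))))
        dh = self.gap.backward(df)
        dh = self.conv3.backward(self.act3.backward(dh))
        dh = self.conv2.backward(self.act2.backward(self.pool2.backward(dh)))
        return self.conv1.backward(self.act1.backward(self.pool1.backward(dh)))
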