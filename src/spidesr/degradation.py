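"""The degradation model: isotropic Gaussian blur, bicubic down-sampling, noise.

Low-resolution observations are modeled as ``I_LR = (K (*) I_HR) v_s + n``:
the high-resolution scene convolved with a blur kernel K, down-sampled by the
scale factor s by sampling a bicubic interpolant, plus optional noise.  The
kernel bank used for training draws the Gaussian width sigma uniformly from
[0.2, 4.0] at a fixed 21x21 support.

Convolution uses reflect padding (avoids dark borders that would bias PSNR
near edges); noise is added after down-sampling; the bicubic step applies no
extra antialias filter beyond K itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import ImageGrid, PatchSet
from .synthetic import NoiseSpec, add_noise

__all__ = [
    "BlurKernel",
    "DegradationConfig",
    "TrainingPairs",
    "gaussian_kernel",
    "degrade",
    "make_training_pairs",
    "kernel_mse",
    "bicubic_resize",
]


@dataclass
class BlurKernel:
    """A nonnegative ``size x size`` kernel summing to 1; optional known width."""

    weights: np.ndarray
    sigma: float | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("kernel must be square")
        if w.shape[0] % 2 == 0:
            raise ValueError("kernel size must be odd")
        if w.min() < -1e-12:
            raise ValueError("kernel weights must be nonnegative")
        s = w.sum()
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"kernel must sum to 1 (got {s})")
        self.weights = w

    @property
    def size(self) -> int:
        return self.weights.shape[0]

    @classmethod
    def from_raw(cls, raw: np.ndarray, sigma: float | None = None) -> "BlurKernel":
        """Clip negatives and renormalize a raw array into a legal kernel."""
        w = np.clip(np.asarray(raw, dtype=np.float64), 0.0, None)
        s = w.sum()
        if s <= 0:
            # degenerate raw output: fall back to a centered delta
            w = np.zeros_like(w)
            w[w.shape[0] // 2, w.shape[1] // 2] = 1.0
            s = 1.0
        return cls(w / s, sigma=sigma)

    def to_text(self, path: str) -> None:
        """Write the kernel as a plain-text matrix; sigma goes in the header."""
        header = f"sigma={self.sigma}" if self.sigma is not None else "sigma=?"
        np.savetxt(path, self.weights, header=header)

    @classmethod
    def from_text(cls, path: str) -> "BlurKernel":
        with open(path) as fh:
            first = fh.readline().strip()
        sigma = None
        if first.startswith("# sigma=") and not first.endswith("?"):
            sigma = float(first.split("=", 1)[1])
        return cls(np.loadtxt(path), sigma=sigma)

    def width_estimate(self) -> float:
        """Isotropic width from the kernel's second moments."""
        c = (self.size - 1) / 2.0
        idx = np.arange(self.size) - c
        var_r = float((self.weights.sum(axis=1) * idx ** 2).sum())
        var_c = float((self.weights.sum(axis=0) * idx ** 2).sum())
        return float(np.sqrt(0.5 * (var_r + var_c)))


@dataclass
class DegradationConfig:
    scale: int = 4
    sigma_range: tuple[float, float] = (0.2, 4.0)
    kernel_size: int = 21
    noise: NoiseSpec | None = None

    def __post_init__(self):
        if self.scale < 1:
            raise ValueError("scale must be >= 1")
        if self.sigma_range[0] <= 0:
            raise ValueError("sigma_range minimum must be > 0")


def gaussian_kernel(sigma: float, size: int = 21) -> BlurKernel:
    """Normalized isotropic Gaussian on a ``size x size`` grid."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if size % 2 == 0:
        raise ValueError("size must be odd")
    c = (size - 1) / 2.0
    idx = np.arange(size) - c
    g = np.exp(-(idx[:, None] ** 2 + idx[None, :] ** 2) / (2.0 * sigma ** 2))
    return BlurKernel(g / g.sum(), sigma=float(sigma))


def _bicubic_sample(chan: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Evaluate the cubic-spline interpolant of ``chan`` on a pixel-center grid."""
    h, w = chan.shape
    rows = (np.arange(out_h) + 0.5) * (h / out_h) - 0.5
    cols = (np.arange(out_w) + 0.5) * (w / out_w) - 0.5
    grid = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(chan, grid, order=3, mode="reflect")


def bicubic_resize(img: ImageGrid, factor: float) -> ImageGrid:
    """Bicubic resize by a positive factor (baseline and size alignment)."""
    if factor <= 0:
        raise ValueError("factor must be > 0")
    h, w = img.shape
    out_h, out_w = max(1, round(h * factor)), max(1, round(w * factor))
    if (out_h, out_w) == (h, w) and factor == 1:
        return img.with_pixels(img.pixels.copy())
    lo, hi = img.value_range
    out = np.stack([_bicubic_sample(ch, out_h, out_w) for ch in img.pixels])
    return img.with_pixels(np.clip(out, lo, hi))


def degrade(hr: ImageGrid, kernel: BlurKernel,
            config: DegradationConfig) -> ImageGrid:
    """Blur with K, bicubic-down-sample by the scale, then add noise if set."""
    h, w = hr.shape
    s = config.scale
    if h % s or w % s:
        raise ValueError(
            f"image dims {h}x{w} not divisible by scale {s}; crop first")
    blurred = np.stack([
        ndimage.convolve(ch, kernel.weights, mode="reflect")
        for ch in hr.pixels])
    if s == 1:
        out = blurred
    else:
        out = np.stack([_bicubic_sample(ch, h // s, w // s) for ch in blurred])
    lo, hi = hr.value_range
    lr = hr.with_pixels(np.clip(out, lo, hi))
    if config.noise is not None:
        lr = add_noise(lr, config.noise)
    return lr


def kernel_mse(a: BlurKernel, b: BlurKernel) -> float:
    """Mean squared element-wise difference between two kernels."""
    if a.size != b.size:
        raise ValueError(f"kernel size mismatch: {a.size} vs {b.size}")
    return float(np.mean((a.weights - b.weights) ** 2))


@dataclass
class TrainingPairs:
    """(hr, lr, kernel) triples with a deterministic 6:2:2 split attached."""

    triples: list[tuple[ImageGrid, ImageGrid, BlurKernel]]
    split: list[str]  # "train" | "val" | "test", aligned with triples

    def subset(self, name: str) -> list[tuple[ImageGrid, ImageGrid, BlurKernel]]:
        return [t for t, s in zip(self.triples, self.split) if s == name]

    @property
    def train(self):
        return self.subset("train")

    @property
    def val(self):
        return self.subset("val")

    @property
    def test(self):
        return self.subset("test")


def make_training_pairs(hr_set: PatchSet, config: DegradationConfig,
                        rng: np.random.Generator) -> TrainingPairs:
    """Degrade each patch with a bank kernel (sigma ~ U[sigma_range]).

    The split is 6:2:2 train/validation/test by a seed-deterministic shuffle.
    """
    if len(hr_set) == 0:
        raise ValueError("hr_set is empty")
    triples = []
    for patch in hr_set:
        sigma = float(rng.uniform(*config.sigma_range))
        k = gaussian_kernel(sigma, config.kernel_size)
        triples.append((patch, degrade(patch, k, config), k))
    n = len(triples)
    order = rng.permutation(n)
    n_train, n_val = int(0.6 * n), int(0.2 * n)
    split = [""] * n
    for pos, i in enumerate(order):
        split[i] = ("train" if pos < n_train
                    else "val" if pos < n_train + n_val else "test")
    return TrainingPairs(triples, split)
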