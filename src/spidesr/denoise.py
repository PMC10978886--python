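"""Self-supervised denoising by neighbor sub-sampling.

A single noisy image ``y`` is split into two half-resolution images
``g1(y), g2(y)`` by drawing, in every 2x2 cell, one of the four
axis-adjacent pixel pairs and dealing its two pixels to g1 and g2 with a
fair coin.  Because paired pixels are neighbors, the two images share
almost the same underlying signal but carry independent noise, so g1 can
serve as input and g2 as target for training a U-net denoiser without any
clean reference.  The loss is

    L = L_rec + gamma * L_reg
    L_rec = || U(g1(y)) - g2(y) ||^2
    L_reg = || U(g1(y)) - g2(y) - (g1(U(y)) - g2(U(y))) ||^2

(mean-squared over pixels), where the regularizer compensates for the small
ground-truth gap between the sub-sampled pair; one sub-sampling realization
is shared by both terms, and by default no gradient flows through the
full-image pass ``U(y)`` (without the stop-gradient the regularizer can
collapse training).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from . import nn
from .io import ImageGrid
from .networks import UNet

__all__ = [
    "SubsampledPair",
    "neighbor_subsample",
    "denoise_loss",
    "NeighborSubsampleDenoiser",
    "train_denoiser",
    "denoise",
]

# the four axis-adjacent pixel pairs inside a 2x2 cell, as (row, col) offsets;
# diagonal pairs are excluded (larger ground-truth gap)
_PAIRS = np.array([
    [[0, 0], [0, 1]],   # top-left  - top-right
    [[0, 0], [1, 0]],   # top-left  - bottom-left
    [[0, 1], [1, 1]],   # top-right - bottom-right
    [[1, 0], [1, 1]],   # bottom-left - bottom-right
])


@dataclass
class SubsampledPair:
    """The (g1, g2) images plus per-pixel source coordinates in y.

    ``provenance[i, j]`` holds ``[[r1, c1], [r2, c2]]``: the pixel of y that
    became g1[i, j] and the one that became g2[i, j].
    """

    g1: ImageGrid
    g2: ImageGrid
    provenance: np.ndarray  # (H/2, W/2, 2, 2) int

    def apply(self, img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Sub-sample another raster of y's shape with the same realization."""
        r1 = self.provenance[:, :, 0, 0]
        c1 = self.provenance[:, :, 0, 1]
        r2 = self.provenance[:, :, 1, 0]
        c2 = self.provenance[:, :, 1, 1]
        if img.ndim == 2:
            return img[r1, c1], img[r2, c2]
        return img[:, r1, c1], img[:, r2, c2]


def neighbor_subsample(y: ImageGrid | np.ndarray,
                       rng: np.random.Generator) -> SubsampledPair:
    """Draw one neighbor sub-sampling realization of ``y`` (k = 2).

    Odd trailing rows/columns are cropped.  For every 2x2 cell one of the
    four 4-adjacent pixel pairs is chosen uniformly; a fair coin assigns the
    pair's pixels to g1 vs g2.  Deterministic under the generator state.
    """
    grid = y if isinstance(y, ImageGrid) else ImageGrid(np.asarray(y, float),
                                                        value_range=(-np.inf, np.inf))
    h, w = grid.shape
    if h < 2 or w < 2:
        raise ValueError("image must be at least 2x2")
    hc, wc = h // 2, w // 2
    choice = rng.integers(0, 4, size=(hc, wc))
    swap = rng.integers(0, 2, size=(hc, wc)).astype(bool)
    offsets = _PAIRS[choice]                          # (hc, wc, 2, 2)
    offsets = np.where(swap[:, :, None, None], offsets[:, :, ::-1, :], offsets)
    base_r = (2 * np.arange(hc))[:, None, None]
    base_c = (2 * np.arange(wc))[None, :, None]
    prov = np.empty((hc, wc, 2, 2), dtype=np.int64)
    prov[:, :, :, 0] = base_r + offsets[:, :, :, 0]
    prov[:, :, :, 1] = base_c + offsets[:, :, :, 1]
    pair = SubsampledPair.__new__(SubsampledPair)
    pair.provenance = prov
    g1_px, g2_px = pair.apply(grid.pixels)
    pair.g1 = grid.with_pixels(g1_px)
    pair.g2 = grid.with_pixels(g2_px)
    return pair


def _loss_terms(net: UNet, y01: np.ndarray, pair: SubsampledPair,
                gamma: float, stop_gradient: bool = True,
                backward: bool = False) -> tuple[float, float]:
    """(L_rec, L_reg) on [0,1]-scaled stacks; optionally backpropagate.

    ``y01``: (N, 1, H, W).  With ``stop_gradient`` the full-image pass U(y)
    inside L_reg is a constant w.r.t. the parameters.
    """
    g1, g2 = pair.apply(y01[:, 0])
    g1 = g1[:, None]
    g2 = g2[:, None]
    if gamma > 0:
        uy = net.forward(y01)                    # caches overwritten below
        g1u, g2u = pair.apply(uy[:, 0])
        target_gap = (g1u - g2u)[:, None]
    out = net.forward(g1)
    diff = out - g2
    npix = diff.size
    l_rec = float(np.mean(diff ** 2))
    if gamma > 0:
        reg_diff = diff - target_gap
        l_reg = float(np.mean(reg_diff ** 2))
    else:
        l_reg = 0.0
    if backward:
        dout = 2.0 * diff / npix
        if gamma > 0:
            dout = dout + gamma * 2.0 * reg_diff / npix
        net.backward(dout)
        if gamma > 0 and not stop_gradient:
            # gradient through U(y): re-run the full-image forward so its
            # caches are live, then scatter the reg gradient back through it
            duy = np.zeros_like(net.forward(y01))
            d_gap = -gamma * 2.0 * reg_diff / npix
            r1 = pair.provenance[:, :, 0, 0]
            c1 = pair.provenance[:, :, 0, 1]
            r2 = pair.provenance[:, :, 1, 0]
            c2 = pair.provenance[:, :, 1, 1]
            for b in range(duy.shape[0]):
                np.add.at(duy[b, 0], (r1, c1), d_gap[b, 0])
                np.add.at(duy[b, 0], (r2, c2), -d_gap[b, 0])
            net.backward(duy)
    return l_rec, l_reg


def denoise_loss(model: "NeighborSubsampleDenoiser", y: ImageGrid,
                 pair: SubsampledPair) -> float:
    """Evaluate L = L_rec + gamma * L_reg for one image and one realization.

    Intensities are scaled to [0, 1] before the squared norms are taken.
    """
    net = model._require_net()
    y01 = y.rescaled().pixels[:, None] / 255.0
    if pair.provenance.shape[:2] != (y.shape[0] // 2, y.shape[1] // 2):
        raise ValueError("pair was not produced from an image of y's shape")
    scale = 1.0 / (255.0 * y.rescale_factor())
    pair01 = SubsampledPair(
        pair.g1.with_pixels((pair.g1.pixels - y.value_range[0]) * scale),
        pair.g2.with_pixels((pair.g2.pixels - y.value_range[0]) * scale),
        pair.provenance)
    l_rec, l_reg = _loss_terms(net, y01, pair01, model.gamma,
                               model.stop_gradient, backward=False)
    return l_rec + model.gamma * l_reg


class NeighborSubsampleDenoiser(BaseEstimator, TransformerMixin):
    """Self-supervised U-net denoiser trained on neighbor-sub-sampled pairs.

    Parameters follow the training recipe: Adam with ``lr`` = 1e-4, batches
    of 4, the learning rate halving every ``lr_halve_every`` epochs, and
    regularization strength ``gamma`` = 1.  The full-scale recipe runs 100
    epochs; the desk-scale default of 20 keeps CPU runs short.

    After :meth:`fit`: ``net_`` (the trained U-net), ``losses_`` (per-epoch
    mean loss), ``n_images_``.
    """

    def __init__(self, base_channels: int = 16, depth: int = 2,
                 gamma: float = 1.0, epochs: int = 20, batch_size: int = 4,
                 lr: float = 1e-4, lr_halve_every: int = 20,
                 stop_gradient: bool = True, random_state: int = 0):
        self.base_channels = base_channels
        self.depth = depth
        self.gamma = gamma
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.lr_halve_every = lr_halve_every
        self.stop_gradient = stop_gradient
        self.random_state = random_state

    # -----------------------------------------------------------------
    def _require_net(self) -> UNet:
        if not hasattr(self, "net_"):
            raise NotFittedError("denoiser is not fitted; call fit() first")
        return self.net_

    @staticmethod
    def _stack(images) -> tuple[np.ndarray, float, float]:
        """Channels-as-samples (N,1,H,W) stack in [0,1] from grids/arrays."""
        chans = []
        for im in images:
            grid = im if isinstance(im, ImageGrid) else ImageGrid(
                np.asarray(im, float), value_range=(0.0, 255.0))
            chans.extend(grid.rescaled().pixels / 255.0)
        shapes = {c.shape for c in chans}
        if len(shapes) > 1:
            raise ValueError(f"training images must share dims, got {shapes}")
        return np.asarray(chans)[:, None]

    def fit(self, X, y=None):
        """Train on a collection of noisy images (no clean references)."""
        if len(X) == 0:
            raise ValueError("training set is empty")
        stack = self._stack(X)
        rng = np.random.default_rng(self.random_state)
        self.net_ = UNet(rng, in_ch=1, base=self.base_channels,
                         depth=self.depth)
        opt = nn.Adam(self.net_.params(), lr=self.lr)
        n = stack.shape[0]
        self.losses_ = []
        self.lr_history_ = []
        for epoch in range(self.epochs):
            opt.lr = self.lr * 0.5 ** (epoch // self.lr_halve_every)
            self.lr_history_.append(opt.lr)
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, self.batch_size):
                batch = stack[order[start:start + self.batch_size]]
                pair = neighbor_subsample(batch[0, 0], rng)
                self.net_.zero_grad()
                l_rec, l_reg = _loss_terms(self.net_, batch, pair, self.gamma,
                                           self.stop_gradient, backward=True)
                opt.step()
                epoch_losses.append(l_rec + self.gamma * l_reg)
            self.losses_.append(float(np.mean(epoch_losses)))
        self.n_images_ = n
        return self

    def transform(self, X):
        """Denoise a collection of images; dims and value ranges preserved."""
        return [self.denoise_one(im) for im in X]

    def denoise_one(self, y) -> ImageGrid:
        net = self._require_net()
        grid = y if isinstance(y, ImageGrid) else ImageGrid(
            np.asarray(y, float), value_range=(0.0, 255.0))
        x01 = grid.rescaled().pixels / 255.0
        mult = 2 ** self.depth
        h, w = x01.shape[1:]
        ph, pw = (-h) % mult, (-w) % mult
        xp = np.pad(x01, ((0, 0), (0, ph), (0, pw)), mode="reflect")
        out = net.forward(xp[:, None])[:, 0, :h, :w]
        lo, hi = grid.value_range
        native = out * 255.0 * grid.rescale_factor() + lo
        return grid.with_pixels(np.clip(native, lo, hi))


    # -----------------------------------------------------------------
    def save(self, path: str) -> None:
        """Serialize parameters and weights to an ``.npz`` checkpoint."""
        import json
        net = self._require_net()
        arrays = {f"w_{i}": a for i, a in enumerate(net.state_list())}
        np.savez(path, __config=json.dumps(self.get_params()), **arrays)

    @classmethod
    def load(cls, path: str) -> "NeighborSubsampleDenoiser":
        import json
        with np.load(path, allow_pickle=False) as data:
            model = cls(**json.loads(str(data["__config"])))
            rng = np.random.default_rng(model.random_state)
            model.net_ = UNet(rng, in_ch=1, base=model.base_channels,
                              depth=model.depth)
            n = len(model.net_.params())
            model.net_.load_state_list([data[f"w_{i}"] for i in range(n)])
        return model


def train_denoiser(training, **config) -> NeighborSubsampleDenoiser:
    """Fit a :class:`NeighborSubsampleDenoiser` on noisy images."""
    return NeighborSubsampleDenoiser(**config).fit(training)


def denoise(model: NeighborSubsampleDenoiser, y) -> ImageGrid:
    """Apply a trained denoiser to one image."""
    return model.denoise_one(y)
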