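"""Raster I/O, patch tiling and training-time augmentation.

Images are carried as :class:`ImageGrid`: one or more single-channel rasters
with bit-depth and value-range metadata.  Coordinates are 0-based, row-major
``(row, col)`` with the origin at top-left.  16-bit acquisitions are linearly
rescaled to [0, 255] floats before entering networks or metrics (the SSIM
stabilizing constants assume a 255 dynamic range); the scale factor is kept
on the grid so quantification can report original-unit values.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["ImageGrid", "PatchSet", "read_image", "write_image", "tile", "augment"]


@dataclass
class ImageGrid:
    """A (C, H, W) stack of intensity rasters with range metadata.

    ``pixels`` is always float64 with shape (channels, rows, cols); a 2-D
    array passed to the constructor is promoted to a single channel.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    value_range: tuple[float, float] | None = None
    channel_names: list[str] | None = None

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim == 2:
            px = px[None]
        if px.ndim != 3:
            raise ValueError(f"pixels must be 2-D or 3-D, got shape {px.shape}")
        self.pixels = px
        if self.value_range is None:
            self.value_range = (0.0, float(2 ** self.bit_depth - 1))
        lo, hi = self.value_range
        if px.size and (px.min() < lo - 1e-9 or px.max() > hi + 1e-9):
            raise ValueError("intensities outside value_range")

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1], self.pixels.shape[2]

    def channel(self, i: int) -> np.ndarray:
        return self.pixels[i]

    def rescaled(self) -> "ImageGrid":
        """Linearly map intensities to the [0, 255] convention."""
        lo, hi = self.value_range
        if (lo, hi) == (0.0, 255.0):
            return self
        px = (self.pixels - lo) * (255.0 / (hi - lo))
        return ImageGrid(px, bit_depth=8, value_range=(0.0, 255.0),
                         channel_names=self.channel_names)

    def rescale_factor(self) -> float:
        """Multiplier taking [0,255]-convention values back to original units."""
        lo, hi = self.value_range
        return (hi - lo) / 255.0

    def with_pixels(self, px: np.ndarray) -> "ImageGrid":
        return ImageGrid(np.asarray(px, dtype=np.float64),
                         bit_depth=self.bit_depth,
                         value_range=self.value_range,
                         channel_names=self.channel_names)


@dataclass
class PatchSet:
    """Equal-sized patches cut from source images, with their origins."""

    patches: list[ImageGrid]
    origins: list[tuple[int, int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.patches)

    def __iter__(self):
        return iter(self.patches)


_DTYPES = {8: np.uint8, 16: np.uint16}


def read_image(path: str | os.PathLike) -> ImageGrid:
    """Read an 8- or 16-bit TIFF into an :class:`ImageGrid`.

    Multi-channel files (planar or interleaved, up to 4 channels) yield one
    raster per channel.
    """
    try:
        arr = tifffile.imread(os.fspath(path))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read TIFF {path!r}: {exc}") from exc
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise ValueError(f"unsupported sample format {arr.dtype} in {path!r}")
    if arr.ndim == 2:
        arr = arr[None]
    elif arr.ndim == 3:
        # interleaved (H, W, C<=4) -> planar
        if arr.shape[-1] <= 4 < arr.shape[0]:
            arr = np.moveaxis(arr, -1, 0)
        if arr.shape[0] > 4:
            raise ValueError(f"more than 4 channels in {path!r}")
    else:
        raise ValueError(f"unsupported TIFF layout {arr.shape} in {path!r}")
    return ImageGrid(arr.astype(np.float64), bit_depth=depth)


def write_image(img: ImageGrid, path: str | os.PathLike) -> None:
    """Write an :class:`ImageGrid` as a TIFF; round-trips bit-exactly."""
    d = os.path.dirname(os.fspath(path))
    if d and not os.path.isdir(d):
        raise OSError(f"directory does not exist: {d!r}")
    dtype = _DTYPES.get(img.bit_depth)
    if dtype is None:
        raise ValueError(f"unsupported bit depth {img.bit_depth}")
    arr = np.rint(img.pixels).astype(dtype)
    if arr.shape[0] == 1:
        arr = arr[0]
    tifffile.imwrite(os.fspath(path), arr, photometric="minisblack")


def tile(img: ImageGrid, patch_size: int) -> PatchSet:
    """Non-overlapping top-left grid tiling; partial strips are discarded."""
    h, w = img.shape
    if patch_size > min(h, w):
        raise ValueError(f"patch_size {patch_size} exceeds image dims {h}x{w}")
    patches, origins = [], []
    for r in range(0, h - patch_size + 1, patch_size):
        for c in range(0, w - patch_size + 1, patch_size):
            patches.append(img.with_pixels(
                img.pixels[:, r:r + patch_size, c:c + patch_size]))
            origins.append((0, r, c))
    return PatchSet(patches, origins)


def augment(img: ImageGrid, rng: np.random.Generator) -> ImageGrid:
    """Random horizontal flip (p=0.5) and rotation by a random multiple of 90 deg."""
    px = img.pixels
    if rng.random() < 0.5:
        px = px[:, :, ::-1]
    k = int(rng.integers(0, 4))
    if k:
        px = np.rot90(px, k=k, axes=(1, 2))
    return img.with_pixels(px.copy())
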