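"""Grey-level size-zone matrix (GLSZM, also called GLZLM) texture features.

A *zone* is a maximal connected component of pixels sharing the same
quantised grey level.  The zone matrix counts zones by (grey level, zone
size): entry (i, j) is the number of zones of level i containing exactly
j pixels.  Rows are fixed at the number of grey levels N; the number of
columns equals the largest zone size present.  Texture statistics are
normalised weighted sums over the matrix:

    SZE  = (1/H) sum_ij  Z[i,j] / j^2      (short-zone emphasis)
    LZE  = (1/H) sum_ij  Z[i,j] * j^2      (long-zone emphasis)
    LGZE = (1/H) sum_ij  Z[i,j] / i^2      (low grey-level emphasis)
    HGZE = (1/H) sum_ij  Z[i,j] * i^2      (high grey-level emphasis)

with H the total number of zones.  Fine, fragmented textures push SZE up;
coarse blobby textures push LZE up; bright-dominated textures push HGZE
up.  Grey levels are 1-based so the low-emphasis weights are finite.

Unlike run-length or co-occurrence matrices the zone matrix needs no
direction parameter, only a connectivity convention (whether diagonal
neighbours join a zone); 8-connectivity is the default here, as in the
wider GLSZM literature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .images import GreyImage

__all__ = [
    "QuantizedImage",
    "ZoneMatrix",
    "TextureFeatures",
    "quantize",
    "build_glzlm",
    "features",
    "feature_map",
    "FEATURE_NAMES",
]

FEATURE_NAMES = ("SZE", "LZE", "LGZE", "HGZE")

_STRUCTURE = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass(frozen=True)
class QuantizedImage:
    """Integer grey levels in [1, N], same shape as the source image."""

    levels: np.ndarray
    N: int

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels)
        if lv.ndim != 2:
            raise ValueError("levels must be 2-D")
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if lv.min() < 1 or lv.max() > self.N:
            raise ValueError(f"levels [{lv.min()}, {lv.max()}] outside [1, {self.N}]")
        object.__setattr__(self, "levels", lv.astype(np.int64))


@dataclass(frozen=True)
class ZoneMatrix:
    """N x S_max zone-count matrix; H is the total zone count."""

    counts: np.ndarray
    N: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != self.N:
            raise ValueError(f"counts must have {self.N} rows, got shape {c.shape}")
        if c.min() < 0:
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def S_max(self) -> int:
        return self.counts.shape[1]

    @property
    def H(self) -> int:
        return int(self.counts.sum())

    @property
    def pixel_count(self) -> int:
        sizes = np.arange(1, self.S_max + 1)
        return int((self.counts * sizes[None, :]).sum())


@dataclass(frozen=True)
class TextureFeatures:
    SZE: float
    LZE: float
    LGZE: float
    HGZE: float
    H: int

    def as_dict(self) -> dict[str, float]:
        return {"SZE": self.SZE, "LZE": self.LZE, "LGZE": self.LGZE, "HGZE": self.HGZE, "H": self.H}


def quantize(
    image: GreyImage,
    N: int = 32,
    value_range: tuple[float, float] | None = None,
) -> QuantizedImage:
    """Uniform-width binning of intensities into N grey levels.

    By default the observed [min, max] range of the image is split into N
    equal bins (levels 1..N).  Pass ``value_range`` for fixed-range binning
    when features must be comparable across images.  A constant image maps
    entirely to level 1.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    g = image.astype_float()
    lo, hi = value_range if value_range is not None else (g.min(), g.max())
    if hi <= lo:
        return QuantizedImage(levels=np.ones_like(g, dtype=np.int64), N=N)
    levels = np.floor((g - lo) / (hi - lo) * N).astype(np.int64) + 1
    return QuantizedImage(levels=np.clip(levels, 1, N), N=N)


def build_glzlm(q: QuantizedImage, connectivity: Literal[4, 8] = 8) -> ZoneMatrix:
    """Count maximal equal-level connected zones by (level, size)."""
    if connectivity not in _STRUCTURE:
        raise ValueError("connectivity must be 4 or 8")
    structure = _STRUCTURE[connectivity]
    n_pixels = q.levels.size
    counts = np.zeros((q.N, n_pixels), dtype=np.int64)
    s_max = 1
    for level in np.unique(q.levels):
        mask = q.levels == level
        labelled, n_zones = ndimage.label(mask, structure=structure)
        if n_zones == 0:
            continue
        sizes = np.bincount(labelled.ravel())[1:]  # label 0 is background
        for s in sizes:
            counts[level - 1, s - 1] += 1
        s_max = max(s_max, int(sizes.max()))
    return ZoneMatrix(counts=counts[:, :s_max], N=q.N)


def features(zm: ZoneMatrix) -> TextureFeatures:
    """The four zone-emphasis statistics of a zone matrix."""
    H = zm.H
    if H == 0:
        raise ValueError("zone matrix is empty (H = 0)")
    c = zm.counts.astype(np.float64)
    i = np.arange(1, zm.N + 1, dtype=np.float64)[:, None]
    j = np.arange(1, zm.S_max + 1, dtype=np.float64)[None, :]
    return TextureFeatures(
        SZE=float((c / j**2).sum() / H),
        LZE=float((c * j**2).sum() / H),
        LGZE=float((c / i**2).sum() / H),
        HGZE=float((c * i**2).sum() / H),
        H=H,
    )


def image_features(
    image: GreyImage,
    N: int = 32,
    connectivity: Literal[4, 8] = 8,
    value_range: tuple[float, float] | None = None,
) -> TextureFeatures:
    """Quantise, build the zone matrix, and return the four features."""
    return features(build_glzlm(quantize(image, N=N, value_range=value_range), connectivity))


def feature_map(
    image: GreyImage,
    window: int = 16,
    stride: int = 8,
    N: int = 8,
    feature: str = "HGZE",
    connectivity: Literal[4, 8] = 8,
) -> GreyImage:
    """Sliding-window map of one zone feature, resized to the input shape.

    Each window is quantised over the *global* intensity range so windows
    are mutually comparable; the resulting coarse grid of feature values is
    bilinearly resized back to the image shape and min-max rescaled to
    [0, max_intensity].  Constant maps (no texture contrast) come back as
    all zeros.
    """
    if feature not in FEATURE_NAMES:
        raise ValueError(f"feature must be one of {FEATURE_NAMES}")
    h, w = image.shape
    if window > min(h, w):
        raise ValueError(f"window {window} larger than image {image.shape}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    g = image.astype_float()
    vrange = (float(g.min()), float(g.max()))
    rows = list(range(0, h - window + 1, stride))
    cols = list(range(0, w - window + 1, stride))
    if rows[-1] != h - window:
        rows.append(h - window)
    if cols[-1] != w - window:
        cols.append(w - window)
    grid = np.zeros((len(rows), len(cols)), dtype=np.float64)
    for ri, r in enumerate(rows):
        for ci, c in enumerate(cols):
            patch = image.with_pixels(g[r : r + window, c : c + window])
            q = quantize(patch, N=N, value_range=vrange)
            grid[ri, ci] = getattr(features(build_glzlm(q, connectivity)), feature)
    full = resize(grid, (h, w), order=1, mode="edge", anti_aliasing=False)
    span = full.max() - full.min()
    if span > 0:
        full = (full - full.min()) / span * image.max_intensity
    else:
        full = np.zeros_like(full)
    return image.with_pixels(full)
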