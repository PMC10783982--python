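"""Seeded generator of trabecular-bone-like binary textures.

Trabecular (spongy) bone is a network of mineralised struts in a marrow
background; its radiographic texture coarsens and thins as bone mineral
density falls.  The generator emulates the two axes of that change with a
stationary random-field model: a seeded white-noise field is smoothed to a
chosen correlation length (coarseness), thresholded at the quantile that
yields a chosen fill fraction (strut density), mapped to two intensity
levels, and degraded with additive Gaussian noise.

This is a texture phantom, not a physical bone simulation: it reproduces
the density/coarseness contrast that zone-size statistics respond to, and
nothing else.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .images import GreyImage, write_image

__all__ = [
    "TextureParams",
    "LabelledDataset",
    "gen_texture",
    "gen_dataset",
    "default_class_params",
    "write_dataset",
]


@dataclass(frozen=True)
class TextureParams:
    """Parameters of one texture class.

    fill_fraction
        Proportion of "bone" pixels, in (0, 1).
    correlation_length
        Gaussian smoothing scale of the latent field, in pixels (> 0).
        Larger values give coarser, blobbier structure.
    bone_level, marrow_level
        Mean intensities of the two phases; bone must be brighter.
    noise_sigma
        Standard deviation of additive Gaussian noise (>= 0), in
        intensity units.
    size
        (height, width) of generated images.
    """

    fill_fraction: float = 0.45
    correlation_length: float = 2.0
    bone_level: float = 200.0
    marrow_level: float = 60.0
    noise_sigma: float = 10.0
    size: tuple[int, int] = (64, 64)
    max_intensity: float = 255.0

    def __post_init__(self) -> None:
        if not 0.0 < self.fill_fraction < 1.0:
            raise ValueError(f"fill_fraction must be in (0,1), got {self.fill_fraction}")
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not self.bone_level > self.marrow_level:
            raise ValueError("bone_level must exceed marrow_level")
        h, w = self.size
        if h < 1 or w < 1:
            raise ValueError(f"size must be positive, got {self.size}")
        if not (0 <= self.marrow_level and self.bone_level <= self.max_intensity):
            raise ValueError("intensity levels outside [0, max_intensity]")


@dataclass(frozen=True)
class LabelledDataset:
    """A balanced, seeded collection of labelled texture images."""

    images: tuple[GreyImage, ...]
    labels: tuple[str, ...]
    seed: int
    params_per_class: Mapping[str, TextureParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must have equal length")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.labels))


def _image_seed(master_seed: int, label: str, index: int) -> np.random.Generator:
    # SeedSequence hashes (master, class, index) so per-image streams are
    # independent of generation order.
    label_key = int.from_bytes(label.encode("utf8"), "little") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), label_key, int(index)]))


def gen_texture(params: TextureParams, seed: int | np.random.Generator) -> GreyImage:
    """Generate one texture image, a pure function of (params, seed)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(int(seed))
    h, w = params.size
    noise = rng.standard_normal((h, w))
    smooth = ndimage.gaussian_filter(noise, sigma=params.correlation_length, mode="wrap")
    # Quantile threshold pins the realised fill fraction exactly (up to the
    # one-pixel granularity of the quantile).
    thresh = np.quantile(smooth, 1.0 - params.fill_fraction)
    bone = smooth > thresh
    img = np.where(bone, params.bone_level, params.marrow_level).astype(np.float64)
    if params.noise_sigma > 0:
        img = img + rng.normal(0.0, params.noise_sigma, size=(h, w))
    img = np.clip(img, 0.0, params.max_intensity)
    return GreyImage(pixels=img, max_intensity=params.max_intensity)


def default_class_params(n_classes: int = 3, size: tuple[int, int] = (64, 64)) -> dict[str, TextureParams]:
    """Shipped class parameter sets.

    Fill fraction decreases and correlation length increases from normal
    bone to osteoporotic bone: fewer, coarser trabecular struts as mineral
    density falls.  Two-class mode keeps the extremes (normal vs
    osteoporotic).
    """
    all_three = {
        "normal": TextureParams(
            fill_fraction=0.55, correlation_length=1.2, noise_sigma=12.0, size=size
        ),
        "osteopenia": TextureParams(
            fill_fraction=0.40, correlation_length=2.0, noise_sigma=12.0, size=size
        ),
        "osteoporotic": TextureParams(
            fill_fraction=0.25, correlation_length=3.0, noise_sigma=12.0, size=size
        ),
    }
    if n_classes == 3:
        return all_three
    if n_classes == 2:
        return {k: all_three[k] for k in ("normal", "osteoporotic")}
    raise ValueError(f"n_classes must be 2 or 3, got {n_classes}")


def gen_dataset(
    params_per_class: Mapping[str, TextureParams],
    n_per_class: int,
    seed: int,
) -> LabelledDataset:
    """Generate a balanced labelled dataset, deterministically from ``seed``."""
    if len(params_per_class) < 2:
        raise ValueError("at least two classes are required")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    images: list[GreyImage] = []
    labels: list[str] = []
    for label, params in params_per_class.items():
        for i in range(n_per_class):
            images.append(gen_texture(params, _image_seed(seed, label, i)))
            labels.append(label)
    return LabelledDataset(
        images=tuple(images),
        labels=tuple(labels),
        seed=int(seed),
        params_per_class=dict(params_per_class),
    )


def write_dataset(
    dataset: LabelledDataset,
    out_dir: str | Path,
    bit_depth: int = 8,
) -> Path:
    """Write images plus a CSV manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = ".png" if bit_depth == 8 else ".tiff"
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["filename", "label", "seed", "fill_fraction", "correlation_length", "noise_sigma"]
        )
        counters: dict[str, int] = {}
        for image, label in zip(dataset.images, dataset.labels):
            idx = counters.get(label, 0)
            counters[label] = idx + 1
            name = f"{label}_{idx:04d}{suffix}"
            write_image(image, out_dir / name, bit_depth=bit_depth)
            p = dataset.params_per_class.get(label)
            writer.writerow(
                [
                    name,
                    label,
                    dataset.seed,
                    p.fill_fraction if p else "",
                    p.correlation_length if p else "",
                    p.noise_sigma if p else "",
                ]
            )
    return manifest
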