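"""Greyscale image container and file I/O.

The pipeline operates on single-channel 2-D rasters.  Intensities are kept
in floating point internally; quantisation back to the source bit depth
happens only when an image is written to disk, so that repeated processing
steps do not accumulate rounding error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import tifffile

VALID_MODALITIES = (None, "CT", "XRAY", "DEXA")


@dataclass(frozen=True)
class GreyImage:
    """A 2-D greyscale intensity raster.

    Parameters
    ----------
    pixels : ndarray
        2-D array of intensities, integer or real.
    max_intensity : float
        Upper bound of the intensity scale (255 for 8-bit sources,
        65535 for 16-bit).  All pixel values must lie in
        ``[0, max_intensity]``.
    modality : str, optional
        Acquisition tag, one of ``"CT"``, ``"XRAY"``, ``"DEXA"``.
    """

    pixels: np.ndarray
    max_intensity: float = 255.0
    modality: Optional[str] = field(default=None)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"pixels must be a non-empty 2-D array, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels contain non-finite values")
        if px.min() < 0 or px.max() > self.max_intensity:
            raise ValueError(
                f"intensities [{px.min()}, {px.max()}] outside [0, {self.max_intensity}]"
            )
        if self.modality not in VALID_MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def astype_float(self) -> np.ndarray:
        return np.asarray(self.pixels, dtype=np.float64)

    def with_pixels(self, pixels: np.ndarray) -> "GreyImage":
        """Return a copy holding ``pixels``, same scale and modality."""
        return GreyImage(pixels=pixels, max_intensity=self.max_intensity, modality=self.modality)


def read_image(path: str | Path, modality: Optional[str] = None) -> GreyImage:
    """Read a PNG or TIFF file as a :class:`GreyImage`.

    Multi-channel files are converted to greyscale by channel averaging.
    The intensity scale is inferred from the stored dtype (255 for 8-bit,
    65535 for 16-bit, 1.0 for floating point).
    """
    path = Path(path)
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.dtype == np.uint8:
        max_intensity = 255.0
    elif arr.dtype == np.uint16:
        max_intensity = 65535.0
    else:
        max_intensity = float(max(1.0, np.max(arr)))
    return GreyImage(pixels=arr.astype(np.float64), max_intensity=max_intensity, modality=modality)


def write_image(image: GreyImage, path: str | Path, bit_depth: int = 8) -> None:
    """Write an image as 8-bit PNG/TIFF or 16-bit TIFF.

    Values are rounded to the target integer grid here and nowhere else.
    """
    path = Path(path)
    if bit_depth == 8:
        scale = 255.0 / image.max_intensity
        arr = np.clip(np.rint(image.astype_float() * scale), 0, 255).astype(np.uint8)
    elif bit_depth == 16:
        scale = 65535.0 / image.max_intensity
        arr = np.clip(np.rint(image.astype_float() * scale), 0, 65535).astype(np.uint16)
    else:
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        if bit_depth == 16:
            raise ValueError("16-bit output requires a TIFF filename")
        iio.imwrite(path, arr)
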