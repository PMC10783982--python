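"""Edge-preserving bilateral (combined domain-range) filtering.

The filter replaces each pixel by a normalised weighted average of its
neighbourhood, where each neighbour's weight is the product of a *domain*
kernel k (geometric closeness) and a *range* kernel s (photometric
similarity):

    f(x) = c(x)^-1 * sum_psi  g(psi) * k(psi - x) * s(g(psi) - g(x))
    c(x) =           sum_psi             k(psi - x) * s(g(psi) - g(x))

Both kernels are Gaussian, exp(-d^2 / 2 sigma^2).  The per-pixel
normaliser c(x) makes the weights sum to one, so a constant (DC) image is
returned unchanged; dropping the range kernel recovers an ordinary
Gaussian low-pass whose constant normaliser c_d plays the same role.
In smooth regions s is nearly flat and the filter averages like a plain
domain filter; across an intensity edge s suppresses the far side of the
edge, which is what preserves it.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np

from .images import GreyImage

__all__ = ["BilateralParams", "domain_filter", "bilateral"]

_BORDER_TO_PAD = {"reflect": "symmetric", "constant": "constant", "edge": "edge"}


@dataclass(frozen=True)
class BilateralParams:
    """Kernel scales and support of the filter.

    sigma_domain
        Spatial Gaussian scale, pixels.
    sigma_range
        Intensity Gaussian scale, intensity units.  Large values make the
        filter converge to the pure domain filter.
    radius
        Half-width of the square support; the window is
        (2*radius+1) x (2*radius+1).  Defaults to ceil(3*sigma_domain).
    border_mode
        One of "reflect", "constant", "edge".
    """

    sigma_domain: float = 2.0
    sigma_range: float | None = None
    radius: int | None = None
    border_mode: str = "reflect"

    def __post_init__(self) -> None:
        if self.sigma_domain <= 0:
            raise ValueError("sigma_domain must be > 0")
        if self.sigma_range is not None and self.sigma_range <= 0:
            raise ValueError("sigma_range must be > 0")
        if self.radius is not None and self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.border_mode not in _BORDER_TO_PAD:
            raise ValueError(f"border_mode must be one of {tuple(_BORDER_TO_PAD)}")

    def effective_radius(self) -> int:
        return self.radius if self.radius is not None else max(1, math.ceil(3.0 * self.sigma_domain))

    def effective_sigma_range(self, max_intensity: float) -> float:
        # Default 10% of the intensity scale: smooths noise-level
        # fluctuations while leaving phase boundaries intact.
        return self.sigma_range if self.sigma_range is not None else 0.1 * max_intensity


def _spatial_kernel(radius: int, sigma_domain: float) -> np.ndarray:
    offsets = np.arange(-radius, radius + 1, dtype=np.float64)
    dy, dx = np.meshgrid(offsets, offsets, indexing="ij")
    return np.exp(-(dy**2 + dx**2) / (2.0 * sigma_domain**2))


def _padded(image: GreyImage, radius: int, border_mode: str) -> np.ndarray:
    g = image.astype_float()
    if not np.all(np.isfinite(g)):
        raise ValueError("image contains non-finite pixels")
    return np.pad(g, radius, mode=_BORDER_TO_PAD[border_mode])


def domain_filter(image: GreyImage, params: BilateralParams) -> GreyImage:
    """Pure spatial (low-pass) filtering with a truncated Gaussian kernel.

    The kernel is normalised by its own sum (the discrete c_d), so constant
    images pass through unchanged.
    """
    radius = params.effective_radius()
    kernel = _spatial_kernel(radius, params.sigma_domain)
    kernel = kernel / kernel.sum()
    padded = _padded(image, radius, params.border_mode)
    h, w = image.shape
    out = np.zeros((h, w), dtype=np.float64)
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            out += kernel[dy + radius, dx + radius] * padded[
                radius + dy : radius + dy + h, radius + dx : radius + dx + w
            ]
    return image.with_pixels(np.clip(out, 0.0, image.max_intensity))


def bilateral(image: GreyImage, params: BilateralParams) -> GreyImage:
    """Combined domain-range filtering.

    Each output pixel is a convex combination of the input intensities in
    its window, so the output range is contained in the input range and no
    clipping is ever needed.
    """
    radius = params.effective_radius()
    sigma_r = params.effective_sigma_range(image.max_intensity)
    spatial = _spatial_kernel(radius, params.sigma_domain)
    padded = _padded(image, radius, params.border_mode)
    g = image.astype_float()
    h, w = image.shape

    num = np.zeros((h, w), dtype=np.float64)
    den = np.zeros((h, w), dtype=np.float64)
    inv_two_sr2 = 1.0 / (2.0 * sigma_r**2)
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            neighbour = padded[radius + dy : radius + dy + h, radius + dx : radius + dx + w]
            weight = spatial[dy + radius, dx + radius] * np.exp(
                -((neighbour - g) ** 2) * inv_two_sr2
            )
            num += weight * neighbour
            den += weight
    # num/den is a convex combination of in-range intensities; the clip
    # only removes last-ulp rounding overshoot
    return image.with_pixels(np.clip(num / den, 0.0, image.max_intensity))
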