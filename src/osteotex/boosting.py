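"""Channel-boosted input construction.

Channel boosting augments a network's input by concatenating *artificial*
channels — each produced by an auxiliary learner, an image-to-image
transform — onto the natural image channels:

    I_B = H_k(I_C, A_1, ..., A_M)

where I_C are the natural channels, A_m the artificial ones, and H_k the
concatenation combiner.  The shipped auxiliary learners reuse the
pipeline's own primitives, so every artificial channel is a deterministic
computation on the input image:

``bilateral``
    Edge-preserving smoothed image (structure without noise).
``residual``
    Detail residual, original minus smoothed (the noise/fine-texture
    component the smoothing removed), affinely shifted to be nonnegative.
``hgze_map``
    Sliding-window high grey-level zone emphasis map (local texture
    coarseness/brightness statistic).

Channels live on heterogeneous scales (intensities vs texture statistics),
so each channel is independently min-max rescaled to [0, 1] before
stacking; the natural channel is rescaled by the image's intensity bound
rather than its observed range, so it stays an exact affine copy of the
input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .bilateral import BilateralParams, bilateral
from .glzlm import feature_map
from .images import GreyImage

__all__ = ["AuxiliaryLearner", "ChannelStack", "boost", "default_learners", "DEFAULT_LEARNER_NAMES"]

DEFAULT_LEARNER_NAMES = ("bilateral", "residual", "hgze_map")


@dataclass(frozen=True)
class AuxiliaryLearner:
    """A named image-to-image transform producing one artificial channel."""

    name: str
    transform: Callable[[GreyImage], GreyImage]
    params: Mapping[str, object] = field(default_factory=dict)

    def __call__(self, image: GreyImage) -> GreyImage:
        out = self.transform(image)
        if out.shape != image.shape:
            raise ValueError(
                f"auxiliary learner {self.name!r} changed shape {image.shape} -> {out.shape}"
            )
        return out


@dataclass(frozen=True)
class ChannelStack:
    """Boosted input: natural channels followed by artificial channels."""

    channels: np.ndarray  # height x width x C, float64 in [0, 1]
    natural_count: int
    provenance: tuple[str, ...]

    def __post_init__(self) -> None:
        ch = np.asarray(self.channels, dtype=np.float64)
        if ch.ndim != 3:
            raise ValueError("channels must be height x width x C")
        if self.natural_count + len(self.provenance) != ch.shape[2]:
            raise ValueError("channel count must equal natural_count + len(provenance)")
        object.__setattr__(self, "channels", ch)

    @property
    def artificial_count(self) -> int:
        return len(self.provenance)

    @property
    def C(self) -> int:
        return self.channels.shape[2]


def _rescale_unit(arr: np.ndarray) -> np.ndarray:
    span = arr.max() - arr.min()
    if span == 0:
        return np.zeros_like(arr)
    return (arr - arr.min()) / span


def boost(image: GreyImage, learners: Sequence[AuxiliaryLearner] = ()) -> ChannelStack:
    """Build the channel-boosted stack for one image.

    Channel 0 is the natural channel (input divided by its intensity
    bound); channels 1..M are the learner outputs in list order, each
    min-max rescaled to [0, 1].
    """
    natural = image.astype_float() / image.max_intensity
    chans = [natural]
    names = []
    for learner in learners:
        out = learner(image)
        chans.append(_rescale_unit(out.astype_float()))
        names.append(learner.name)
    return ChannelStack(
        channels=np.stack(chans, axis=2), natural_count=1, provenance=tuple(names)
    )


def _make_bilateral(params: BilateralParams) -> Callable[[GreyImage], GreyImage]:
    return lambda img: bilateral(img, params)


def _make_residual(params: BilateralParams) -> Callable[[GreyImage], GreyImage]:
    def residual(img: GreyImage) -> GreyImage:
        diff = img.astype_float() - bilateral(img, params).astype_float()
        # shift into the valid intensity range; per-channel rescaling in
        # boost() removes the offset again
        shifted = diff - diff.min()
        return img.with_pixels(np.clip(shifted, 0.0, img.max_intensity))

    return residual


def _make_hgze_map(window: int, stride: int, N: int) -> Callable[[GreyImage], GreyImage]:
    return lambda img: feature_map(img, window=window, stride=stride, N=N, feature="HGZE")


def default_learners(config: Mapping[str, object] | None = None) -> list[AuxiliaryLearner]:
    """The shipped auxiliary learner set (subset-selectable via config).

    ``config`` keys: ``learners`` (ordered name list), ``bilateral``
    (BilateralParams kwargs), ``hgze_map`` (window/stride/N kwargs).
    """
    config = dict(config or {})
    names = list(config.get("learners", DEFAULT_LEARNER_NAMES))
    bparams = BilateralParams(**dict(config.get("bilateral", {})))
    hkw = {"window": 16, "stride": 8, "N": 8}
    hkw.update(dict(config.get("hgze_map", {})))

    factory = {
        "bilateral": lambda: AuxiliaryLearner("bilateral", _make_bilateral(bparams)),
        "residual": lambda: AuxiliaryLearner("residual", _make_residual(bparams)),
        "hgze_map": lambda: AuxiliaryLearner("hgze_map", _make_hgze_map(**hkw), params=dict(hkw)),
    }
    out = []
    for name in names:
        if name not in factory:
            raise ValueError(f"unknown learner {name!r}; known: {sorted(factory)}")
        out.append(factory[name]())
    return out


def boost_dataset(images: Sequence[GreyImage], learners: Sequence[AuxiliaryLearner]) -> np.ndarray:
    """Stack boosted inputs for many images: n x height x width x C."""
    return np.stack([boost(img, learners).channels for img in images], axis=0)
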