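"""Per-pixel color rules for DAB immunohistochemistry images.

Two decisions are made for every pixel of an 8-bit RGB image:

1. *Background vs. sample.* Slide background is near-white: all three
   channels are high and nearly equal. A pixel is background when its
   minimum channel is at least ``bg_min`` (default 230) and the channel
   spread ``max - min`` does not exceed ``bg_uniformity`` (default 25).
   Everything else is tissue.

2. *Stained vs. unstained sample.* Hematoxylin counterstain leaves tissue
   blue-dominant, while DAB chromogen turns it brown (red-dominant and
   dark). A sample pixel is called stained when at least one channel is
   strictly below ``dark_threshold`` (default 125) *and* blue is not the
   dominant channel, where blue dominance means ``B >= alpha*R`` and
   ``B >= beta*G`` with defaults ``(alpha, beta) = (1.00, 1.25)``.

The rules are deliberately simple, deterministic and stateless: they
depend only on the pixel value and the parameter set, which makes the
vectorized implementation checkable against a naive scalar loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .quant import StainQuant

__all__ = [
    "PixelClassParams",
    "PixelLabel",
    "is_background",
    "is_stained",
    "classify_pixel",
    "background_mask",
    "stain_mask",
    "classify_image",
]


class PixelLabel(IntEnum):
    """Mutually exclusive, exhaustive pixel categories."""

    BACKGROUND = 0
    SAMPLE_UNSTAINED = 1
    SAMPLE_STAINED = 2


@dataclass(frozen=True)
class PixelClassParams:
    """Thresholds for the background and stain rules.

    Parameters
    ----------
    bg_min : int
        Minimum channel intensity for background; near-white slide glass
        typically exceeds 230.
    bg_uniformity : int
        Maximum allowed ``max - min`` channel spread for background.
        Chromatic (tissue) pixels exceed this even when bright.
    dark_threshold : int
        A sample pixel can only be stained if at least one channel is
        strictly below this value.
    alpha, beta : float
        Scales applied to R and G when testing blue dominance:
        blue dominates iff ``B >= alpha*R`` and ``B >= beta*G``.
    """

    bg_min: int = 230
    bg_uniformity: int = 25
    dark_threshold: int = 125
    alpha: float = 1.00
    beta: float = 1.25

    def __post_init__(self) -> None:
        if not (0 < self.bg_min <= 255):
            raise ValueError(f"bg_min must be in (0, 255], got {self.bg_min}")
        if self.bg_uniformity < 0:
            raise ValueError("bg_uniformity must be >= 0")
        if not (0 < self.dark_threshold < 255):
            raise ValueError("dark_threshold must be in (0, 255)")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")


def is_background(pixel, params: PixelClassParams = PixelClassParams()) -> bool:
    """True when a pixel is near-white slide background.

    ``pixel`` is an ``(r, g, b)`` triple of 8-bit intensities.
    """
    r, g, b = (int(c) for c in pixel)
    lo = min(r, g, b)
    hi = max(r, g, b)
    return lo >= params.bg_min and (hi - lo) <= params.bg_uniformity


def is_stained(pixel, params: PixelClassParams = PixelClassParams()) -> bool:
    """True when a *sample* pixel carries brown DAB stain.

    Only meaningful for pixels already determined not to be background;
    callers must not interpret the result on background pixels.

    The pixel is stained iff some channel is strictly below
    ``dark_threshold`` and blue is not dominant. Blue dominance uses
    non-strict comparisons (``B >= alpha*R and B >= beta*G``) so exact
    ties count as unstained, biasing against false-positive stain calls.
    """
    r, g, b = (int(c) for c in pixel)
    if min(r, g, b) >= params.dark_threshold:
        return False
    blue_dominant = b >= params.alpha * r and b >= params.beta * g
    return not blue_dominant


def classify_pixel(pixel, params: PixelClassParams = PixelClassParams()) -> PixelLabel:
    """Assign one of the three labels to a single pixel."""
    if is_background(pixel, params):
        return PixelLabel.BACKGROUND
    if is_stained(pixel, params):
        return PixelLabel.SAMPLE_STAINED
    return PixelLabel.SAMPLE_UNSTAINED


def _as_rgb_array(img) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 RGB raster, got shape {arr.shape}")
    if arr.shape[0] == 0 or arr.shape[1] == 0:
        raise ValueError("empty image")
    return arr.astype(np.int16, copy=False)


def background_mask(img, params: PixelClassParams = PixelClassParams()) -> np.ndarray:
    """Boolean H x W mask of background pixels (vectorized rule 1)."""
    arr = _as_rgb_array(img)
    lo = arr.min(axis=2)
    hi = arr.max(axis=2)
    return (lo >= params.bg_min) & ((hi - lo) <= params.bg_uniformity)


def stain_mask(img, params: PixelClassParams = PixelClassParams()) -> np.ndarray:
    """Boolean H x W mask of the stain rule applied to every pixel.

    Apply only where ``~background_mask``; the rule is not meaningful on
    background pixels.
    """
    arr = _as_rgb_array(img)
    r = arr[..., 0].astype(np.float64)
    g = arr[..., 1].astype(np.float64)
    b = arr[..., 2].astype(np.float64)
    dark = arr.min(axis=2) < params.dark_threshold
    blue_dominant = (b >= params.alpha * r) & (b >= params.beta * g)
    return dark & ~blue_dominant


def classify_image(
    img, params: PixelClassParams = PixelClassParams()
) -> tuple[np.ndarray, StainQuant]:
    """Label every pixel of an RGB image and tally the categories.

    Returns
    -------
    labels : ndarray of uint8, shape (H, W)
        Values from :class:`PixelLabel`.
    quant : StainQuant
        Pixel tallies satisfying the conservation identities
        ``background + sample == total`` and
        ``stained + unstained == sample``.
    """
    bg = background_mask(img, params)
    stained = stain_mask(img, params) & ~bg
    labels = np.full(bg.shape, PixelLabel.SAMPLE_UNSTAINED, dtype=np.uint8)
    labels[bg] = PixelLabel.BACKGROUND
    labels[stained] = PixelLabel.SAMPLE_STAINED

    total = labels.size
    n_bg = int(bg.sum())
    n_stained = int(stained.sum())
    n_sample = total - n_bg
    quant = StainQuant(
        total_pixels=total,
        background_pixels=n_bg,
        sample_pixels=n_sample,
        stained_pixels=n_stained,
        unstained_pixels=n_sample - n_stained,
    )
    return labels, quant
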