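"""Synthetic IHC images, TMA layouts and marker tables with exact ground truth.

Every generator emits colors that the pixel rules classify exactly as
labeled (verified by rejection sampling at generation time), and target
fractions are realized by placing exact pixel counts rather than by
independent per-pixel sampling — so recovery tests are exact, not
statistical.

Color models (rule-consistent by construction, plausible in appearance):
background near-white with small channel spread; unstained tissue around
the hematoxylin hue with blue the dominant channel (B >= 1.25 G and
B >= R); stained tissue around the DAB brown hue with red dominant, blue
below red, and at least one channel dark.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pixels import PixelClassParams, PixelLabel, classify_image
from .stats import MarkerPair

__all__ = [
    "TissueImageSpec",
    "TMALayoutSpec",
    "gen_tissue_image",
    "gen_tma_image",
    "gen_marker_pairs",
    "sample_colors",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TissueImageSpec:
    """Flat tissue image: target tissue and stain fractions, exact counts."""

    width: int = 100
    height: int = 100
    stain_fraction_target: float = 0.2  # of tissue pixels
    tissue_fraction_target: float = 0.5  # of all pixels
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("stain_fraction_target", "tissue_fraction_target"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.width < 1 or self.height < 1:
            raise ValueError("image dimensions must be positive")


@dataclass(frozen=True)
class TMALayoutSpec:
    """Regular TMA grid of circular cores with controlled imperfections.

    ``jitter_fraction`` displaces each core uniformly by up to that
    fraction of the spacing per axis; ``missing_prob`` drops cores;
    ``fragment_prob`` renders a core as two half-disks separated by a
    3-px gap; ``debris_count`` adds small specks below any sensible
    core-area threshold. ``upscale`` is the integer factor between the
    thumbnail and the full-resolution image.
    """

    grid_rows: int = 3
    grid_cols: int = 3
    spacing: int = 100
    core_radius: int = 30
    jitter_fraction: float = 0.0
    missing_prob: float = 0.0
    fragment_prob: float = 0.0
    debris_count: int = 0
    upscale: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.core_radius < self.spacing / 2:
            raise ValueError("core_radius must be smaller than spacing / 2")
        for name in ("jitter_fraction", "missing_prob", "fragment_prob"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        # worst-case gap between adjacent cores after opposing jitter
        min_gap = self.spacing - 2 * self.jitter_fraction * self.spacing - 2 * self.core_radius
        if min_gap <= 0:
            raise ValueError(
                "cores would overlap: jitter too large for the spacing "
                f"(worst-case gap {min_gap:.1f} px)"
            )
        if self.upscale < 1:
            raise ValueError("upscale must be >= 1")


# ---------------------------------------------------------------------------
# color sampling


def _background_colors(rng: np.random.Generator, n: int) -> np.ndarray:
    base = rng.integers(240, 251, size=(n, 1))
    jitter = rng.integers(0, 6, size=(n, 3))
    return np.minimum(base + jitter, 255).astype(np.uint8)


def _unstained_colors(rng: np.random.Generator, n: int) -> np.ndarray:
    # hematoxylin blue: B dominant (B >= 1.25 G, B >= R), not near-white
    g = rng.integers(60, 150, size=n)
    b = np.minimum(np.ceil(1.25 * g).astype(int) + rng.integers(0, 25, size=n), 255)
    r = rng.integers(40, 1 + np.minimum(b, 220))
    return np.stack([r, g, b], axis=1).astype(np.uint8)


def _stained_colors(rng: np.random.Generator, n: int) -> np.ndarray:
    # DAB brown: R dominant, B < R and dark, at least one channel < 125
    r = rng.integers(100, 201, size=n)
    b = rng.integers(30, np.minimum(r - 1, 120))
    g = rng.integers(40, 171, size=n)
    return np.stack([r, g, b], axis=1).astype(np.uint8)


_SAMPLERS = {
    PixelLabel.BACKGROUND: _background_colors,
    PixelLabel.SAMPLE_UNSTAINED: _unstained_colors,
    PixelLabel.SAMPLE_STAINED: _stained_colors,
}


def sample_colors(
    label: PixelLabel,
    n: int,
    rng: np.random.Generator,
    params: PixelClassParams = PixelClassParams(),
) -> np.ndarray:
    """Draw ``n`` colors of a class, rejection-verified against the rules.

    Any drawn color the classifier would mislabel is resampled; if more
    than 99% of draws are rejected the color model is incompatible with
    the parameter set and generation fails.
    """
    from .pixels import classify_pixel

    out = np.empty((n, 3), dtype=np.uint8)
    filled = 0
    drawn = 0
    while filled < n:
        batch = _SAMPLERS[label](rng, n - filled)
        drawn += len(batch)
        ok = np.fromiter(
            (classify_pixel(px, params) == label for px in batch),
            dtype=bool,
            count=len(batch),
        )
        kept = batch[ok]
        out[filled : filled + len(kept)] = kept
        filled += len(kept)
        if drawn >= 100 * n and filled < n:
            raise RuntimeError(
                f"color model for {label.name} rejected >99% of draws under {params}"
            )
    return out


# ---------------------------------------------------------------------------
# flat tissue images


def gen_tissue_image(
    spec: TissueImageSpec, params: PixelClassParams = PixelClassParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Generate a tissue image plus its per-pixel ground-truth labels.

    Pixel counts are exact: ``round(tissue_fraction * N)`` tissue pixels
    of which ``round(stain_fraction * n_tissue)`` are stained, placed at
    shuffled positions.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.width * spec.height
    n_tissue = round(spec.tissue_fraction_target * n)
    n_stained = round(spec.stain_fraction_target * n_tissue)

    labels = np.full(n, PixelLabel.BACKGROUND, dtype=np.uint8)
    pos = rng.permutation(n)
    labels[pos[:n_stained]] = PixelLabel.SAMPLE_STAINED
    labels[pos[n_stained:n_tissue]] = PixelLabel.SAMPLE_UNSTAINED

    img = np.empty((n, 3), dtype=np.uint8)
    for lab in PixelLabel:
        mask = labels == lab
        cnt = int(mask.sum())
        if cnt:
            img[mask] = sample_colors(lab, cnt, rng, params)
    return (
        img.reshape(spec.height, spec.width, 3),
        labels.reshape(spec.height, spec.width),
    )


# ---------------------------------------------------------------------------
# TMA scenes


def gen_tma_image(
    spec: TMALayoutSpec, params: PixelClassParams = PixelClassParams()
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Generate a TMA thumbnail, its integer-upscaled full image, and truth.

    The ground-truth table has one row per designed grid position:
    ``row, col`` (1-based), thumbnail centroid, ``present``,
    ``fragmented`` and the core's stain fraction (exact pixel counts
    within the rendered disk).
    """
    rng = np.random.default_rng(spec.seed)
    h = spec.spacing * (spec.grid_rows + 1)
    w = spec.spacing * (spec.grid_cols + 1)
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = _background_colors(rng, h * w).reshape(h, w, 3)

    yy, xx = np.mgrid[0:h, 0:w]
    truth_rows = []
    for r in range(spec.grid_rows):
        for c in range(spec.grid_cols):
            cx = spec.spacing * (c + 1)
            cy = spec.spacing * (r + 1)
            jmax = spec.jitter_fraction * spec.spacing
            if jmax > 0:
                cx += rng.uniform(-jmax, jmax)
                cy += rng.uniform(-jmax, jmax)
            cx, cy = int(round(cx)), int(round(cy))
            present = rng.random() >= spec.missing_prob
            fragmented = present and rng.random() < spec.fragment_prob
            stain_frac = float(rng.uniform(0.1, 0.6))
            if present:
                disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= spec.core_radius**2
                if fragmented:
                    # two half-disks separated by a 3-px vertical gap
                    disk &= np.abs(xx - cx) > 1
                idx = np.flatnonzero(disk.ravel())
                n_px = idx.size
                n_st = round(stain_frac * n_px)
                order = rng.permutation(n_px)
                flat = img.reshape(-1, 3)
                flat[idx[order[:n_st]]] = sample_colors(
                    PixelLabel.SAMPLE_STAINED, n_st, rng, params
                )
                flat[idx[order[n_st:]]] = sample_colors(
                    PixelLabel.SAMPLE_UNSTAINED, n_px - n_st, rng, params
                )
                stain_frac_real = n_st / n_px if n_px else np.nan
            else:
                stain_frac_real = np.nan
            truth_rows.append(
                {
                    "row": r + 1,
                    "col": c + 1,
                    "centroid_x": cx,
                    "centroid_y": cy,
                    "present": present,
                    "fragmented": fragmented,
                    "stain_fraction": stain_frac_real,
                }
            )

    # debris: specks far smaller than any plausible core
    for _ in range(spec.debris_count):
        dx = int(rng.integers(5, w - 5))
        dy = int(rng.integers(5, h - 5))
        speck = (xx - dx) ** 2 + (yy - dy) ** 2 <= 2**2
        img.reshape(-1, 3)[np.flatnonzero(speck.ravel())] = sample_colors(
            PixelLabel.SAMPLE_UNSTAINED, int(speck.sum()), rng, params
        )

    full = np.repeat(np.repeat(img, spec.upscale, axis=0), spec.upscale, axis=1)
    return img, full, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# marker tables


def gen_marker_pairs(
    n_low: int,
    n_high: int,
    pvi_low_mean: float,
    pvi_high_mean: float,
    noise_sd: float,
    seed: int = 0,
) -> list[MarkerPair]:
    """Simulate paired Ki-67/CD31 stain fractions for two Gleason groups.

    CD31 fractions come from a fixed positive uniform distribution
    (0.02-0.08, typical vascular stain area); each sample's PVI is its
    group mean times multiplicative lognormal noise of scale
    ``noise_sd`` (``noise_sd=0`` makes every PVI exactly the group
    mean); Ki-67 = PVI * CD31. Gleason labels are 6/7 for the low group
    and 8/9 for the high group. Fractions falling outside [0, 1] are
    clipped with a warning.
    """
    if pvi_low_mean <= 0 or pvi_high_mean <= 0:
        raise ValueError("PVI means must be positive")
    if n_low < 2 or n_high < 2:
        raise ValueError("need at least 2 samples per group")
    rng = np.random.default_rng(seed)
    pairs = []
    for grp, n, mean in (("low", n_low, pvi_low_mean), ("high", n_high, pvi_high_mean)):
        cd31 = rng.uniform(0.02, 0.08, size=n)
        noise = rng.lognormal(0.0, noise_sd, size=n) if noise_sd > 0 else np.ones(n)
        pvi = mean * noise
        ki67 = pvi * cd31
        if np.any(ki67 > 1):
            warnings.warn("ki67 fractions above 1 clipped; reduce means or noise")
            ki67 = np.clip(ki67, 0, 1)
        gleason = rng.choice([6, 7] if grp == "low" else [8, 9], size=n)
        for i in range(n):
            pairs.append(
                MarkerPair(
                    sample_id=f"{grp}-{i:03d}",
                    ki67_fraction=float(ki67[i]),
                    cd31_fraction=float(cd31[i]),
                    gleason=int(gleason[i]),
                )
            )
    return pairs
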