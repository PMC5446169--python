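"""ROI and whole-block stain quantification.

An ROI crop is classified in one pass. Whole-block scans are large, so
they are split by a fixed grid (default 4 x 4, sixteen tiles) and the
tiles are classified sequentially, accumulating tallies; only one tile
is resident at a time. Tiling is purely a memory strategy — the
cumulative result is exactly, integer for integer, the single-pass
result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pixels import PixelClassParams, PixelLabel, classify_image
from .quant import StainQuant

__all__ = [
    "TileConfig",
    "quantify_roi",
    "tile_image",
    "quantify_whole_block",
    "normalize_by_max",
    "quantify_batch",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TileConfig:
    """Grid shape for tiled whole-block processing (default 4 x 4)."""

    grid_rows: int = 4
    grid_cols: int = 4

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be >= 1")


def quantify_roi(
    img,
    params: PixelClassParams = PixelClassParams(),
    return_masks: bool = False,
):
    """Quantify stain in a region-of-interest image.

    Parameters
    ----------
    img : H x W x 3 uint8 array
    return_masks : bool
        When True, also return the two binary composite rasters: the
        sample mask (tissue white, background black) and the stain mask
        (stained tissue white).

    Returns
    -------
    StainQuant, or ``(StainQuant, sample_mask, stain_mask)``.
    """
    labels, quant = classify_image(img, params)
    if not return_masks:
        return quant
    sample_mask = labels != PixelLabel.BACKGROUND
    stained_mask = labels == PixelLabel.SAMPLE_STAINED
    return quant, sample_mask, stained_mask


def tile_image(shape, cfg: TileConfig = TileConfig()):
    """Partition an image of ``shape = (H, W)`` into grid-aligned tiles.

    Tile heights and widths are the floor division of the image
    dimensions by the grid; the last row and column of tiles absorb any
    remainder so the tiles are pairwise disjoint and cover the image
    exactly.

    Returns a row-major list of ``(row_start, row_stop, col_start,
    col_stop)`` half-open rectangles, ``grid_rows * grid_cols`` of them.
    """
    h, w = int(shape[0]), int(shape[1])
    if h < cfg.grid_rows or w < cfg.grid_cols:
        raise ValueError(
            f"image of shape ({h}, {w}) is smaller than the "
            f"{cfg.grid_rows} x {cfg.grid_cols} grid"
        )
    th, tw = h // cfg.grid_rows, w // cfg.grid_cols
    tiles = []
    for i in range(cfg.grid_rows):
        r0 = i * th
        r1 = (i + 1) * th if i < cfg.grid_rows - 1 else h
        for j in range(cfg.grid_cols):
            c0 = j * tw
            c1 = (j + 1) * tw if j < cfg.grid_cols - 1 else w
            tiles.append((r0, r1, c0, c1))
    return tiles


def quantify_whole_block(
    img,
    params: PixelClassParams = PixelClassParams(),
    cfg: TileConfig = TileConfig(),
) -> StainQuant:
    """Quantify a whole-block image tile by tile with cumulative totals.

    ``img`` may be an in-memory array or a path to a raster file; paths
    are opened memory-mapped where the format allows so that only the
    tile being processed is resident.
    """
    if isinstance(img, (str, Path)):
        from .io import read_image_lazy

        img = read_image_lazy(img)
    arr = img
    total = StainQuant.zero()
    for r0, r1, c0, c1 in tile_image(arr.shape[:2], cfg):
        tile = np.asarray(arr[r0:r1, c0:c1])
        _, q = classify_image(tile, params)
        total = total + q
    return total


def normalize_by_max(values: Sequence[float]) -> list[float]:
    """Divide each stain fraction by the maximum of the list.

    Used to compare measurement series on a common relative scale: the
    sample with the highest stain concentration maps to 1.0.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("cannot normalize an empty list")
    m = max(vals)
    if m <= 0:
        raise ValueError("cannot normalize: maximum value is not positive")
    return [v / m for v in vals]


def quantify_batch(
    paths: Sequence,
    params: PixelClassParams = PixelClassParams(),
    cfg: TileConfig | None = None,
    marker: str = "",
) -> pd.DataFrame:
    """Quantify every image in ``paths``; one output row per image.

    Results are independent of processing order; rows are sorted by
    image id. With a ``TileConfig`` the images are processed tiled
    (whole-block mode), otherwise in one pass (ROI mode).
    """
    from .io import read_image

    rows = []
    for p in paths:
        p = Path(p)
        if cfg is not None:
            q = quantify_whole_block(p, params, cfg)
        else:
            q = quantify_roi(read_image(p), params)
        frac = q.stain_fraction
        rows.append(
            {
                "image_id": p.stem,
                "marker": marker,
                "total_pixels": q.total_pixels,
                "sample_pixels": q.sample_pixels,
                "stained_pixels": q.stained_pixels,
                "stain_fraction": np.nan if frac is None else frac,
            }
        )
        if frac is None:
            log.warning("image %s contains no sample tissue", p)
    return pd.DataFrame(rows).sort_values("image_id", ignore_index=True)
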