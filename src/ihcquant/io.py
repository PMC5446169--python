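"""Raster and table I/O plus pipeline orchestration.

Supported raster formats: TIFF (including large flat TIFF), PNG, JPEG.
Images are normalized to 8-bit 3-channel RGB on read: alpha channels are
dropped and 16-bit data rescaled, each with a logged warning. Pyramidal
whole-slide formats (e.g. SVS) are not read directly; export a flat
TIFF from the slide viewer first.

CSV is the canonical table format; ``.xlsx`` is honored where a path
with that suffix is given.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .pixels import PixelClassParams
from .slides import TileConfig, quantify_batch
from .tma import DearrayParams, dearray, export_results

__all__ = ["read_image", "read_image_lazy", "write_image", "read_annotations", "RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)

_RASTER_SUFFIXES = {".tif", ".tiff", ".png", ".jpg", ".jpeg"}


def _normalize(arr: np.ndarray, path) -> np.ndarray:
    if arr.ndim == 2:
        raise IOError(f"{path}: grayscale images are not supported; need RGB")
    if arr.ndim != 3:
        raise IOError(f"{path}: unsupported raster shape {arr.shape}")
    if arr.shape[2] == 4:
        log.warning("%s: dropping alpha channel", path)
        arr = arr[..., :3]
    elif arr.shape[2] != 3:
        raise IOError(f"{path}: expected 3 or 4 channels, got {arr.shape[2]}")
    if arr.dtype == np.uint16:
        log.warning("%s: rescaling 16-bit data to 8-bit", path)
        arr = (arr / 257.0).round().astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise IOError(f"{path}: unsupported dtype {arr.dtype}")
    return arr


def read_image(path) -> np.ndarray:
    """Read a raster file into an H x W x 3 uint8 array."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"{path}: no such file")
    if path.suffix.lower() not in _RASTER_SUFFIXES:
        raise IOError(f"{path}: unsupported format {path.suffix!r}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = np.asarray(Image.open(path))
    except Exception as e:  # truncated / corrupt files
        raise IOError(f"{path}: failed to read ({e})") from e
    return _normalize(np.asarray(arr), path)


def read_image_lazy(path) -> np.ndarray:
    """Read a raster for tiled processing, memory-mapping where possible.

    Flat uncompressed TIFFs are memory-mapped so that whole-block
    tiling touches one tile at a time; other formats fall back to an
    ordinary in-memory read.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        try:
            arr = tifffile.memmap(path)
            return _normalize(arr, path)
        except (ValueError, MemoryError):
            log.debug("%s: not memory-mappable, reading into memory", path)
    return read_image(path)


def write_image(arr: np.ndarray, path) -> None:
    """Write an H x W x 3 uint8 raster as PNG/TIFF/JPEG by suffix."""
    path = Path(path)
    arr = np.ascontiguousarray(arr, dtype=np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def read_annotations(path) -> pd.DataFrame:
    """Read a TMA annotation table (row, col, gleason) from CSV or xlsx."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path)


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    inputs: list = field(default_factory=list)  # image paths
    mode: str = "roi"  # roi | wholeblock | tma
    out_dir: Path = Path(".")
    marker: str = ""
    params: PixelClassParams = field(default_factory=PixelClassParams)
    tiles: TileConfig = field(default_factory=TileConfig)
    dearray_params: DearrayParams | None = None
    annotation_path: Path | None = None
    thumb_path: Path | None = None  # TMA mode: thumbnail raster
    seed: int = 0

    def validate(self) -> None:
        for p in list(self.inputs) + [self.annotation_path, self.thumb_path]:
            if p is not None and not Path(p).exists():
                raise IOError(f"configured path does not exist: {p}")
        if self.mode not in ("roi", "wholeblock", "tma"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "tma" and self.dearray_params is None:
            raise ValueError("tma mode requires DearrayParams (grid design)")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run one pipeline stage and write its outputs plus a run manifest.

    Returns the manifest dict (also written as ``manifest.json`` in the
    output directory). Outputs are deterministic for a given config.
    """
    from . import __version__

    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "mode": cfg.mode,
        "inputs": [str(p) for p in cfg.inputs],
        "params": vars(cfg.params).copy(),
        "seed": cfg.seed,
        "outputs": [],
    }

    if cfg.mode in ("roi", "wholeblock"):
        tiles = cfg.tiles if cfg.mode == "wholeblock" else None
        df = quantify_batch(cfg.inputs, cfg.params, tiles, marker=cfg.marker)
        out = out_dir / "stain_quant.csv"
        df.to_csv(out, index=False)
        manifest["outputs"].append(str(out))
        manifest["n_images"] = len(df)
    else:
        thumb = read_image(cfg.thumb_path)
        full = read_image_lazy(cfg.inputs[0])
        annot = read_annotations(cfg.annotation_path) if cfg.annotation_path else None
        records = dearray(thumb, full, cfg.dearray_params, cfg.params, annotations=annot)
        out = out_dir / "tma_cores.csv"
        export_results(records, out)
        manifest["outputs"].append(str(out))
        manifest["n_cores"] = len(records)

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
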