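"""Tissue-microarray de-arraying: detect cores, assign grid positions,
score each core, join pathologist annotations, export a results table.

The workflow operates on two rasters of the same scene: a thumbnail,
small enough for in-memory morphology, on which cores are detected and
gridded; and the full-resolution image, onto which core centroids are
scaled for per-core stain scoring.

Detection: tissue (non-background) pixels form the foreground mask;
morphological closing with a disk merges fragmented cores; hole filling
solidifies them; connected components outside an area window are
discarded (debris, merged core pairs).

Gridding: inter-core spacing is estimated as the median nearest-neighbor
centroid distance. The core nearest the image origin (minimal x + y)
anchors a walk down the first column, accepting at each step the nearest
centroid whose horizontal offset stays within ``col_tolerance * spacing``
and whose vertical offset falls within ``spacing_window`` times
``k * spacing``, expanding the gap ``k = 1, 2, ...`` past missing cores.
If the first column yields too few cores the first row is used as the
baseline instead. Each baseline core then anchors the same walk along
its row (or column). A final reconciliation pass places any centroid the
walks missed — e.g. a core whose baseline anchor is absent — into the
nearest empty cell predicted from the already-assigned grid geometry,
under the same tolerance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure, morphology

from .pixels import PixelClassParams, background_mask, classify_image
from .quant import StainQuant

__all__ = [
    "CoreBlob",
    "DearrayParams",
    "CoreRecord",
    "detect_cores",
    "build_centroid_table",
    "find_origin_core",
    "estimate_spacing",
    "assemble_grid",
    "invert_grid_labels",
    "scale_centroids",
    "score_core",
    "join_annotations",
    "export_results",
    "dearray",
]

log = logging.getLogger(__name__)

EMPTY = -1  # empty-cell marker in the location matrix


@dataclass(frozen=True)
class CoreBlob:
    """One detected core candidate on the thumbnail."""

    centroid_x: float  # horizontal (column) position, pixels
    centroid_y: float  # vertical (row) position, pixels
    area: int  # pixels^2

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("blob area must be positive")


@dataclass
class DearrayParams:
    """TMA design declaration plus detection/gridding tolerances.

    ``grid_rows`` and ``grid_cols`` describe the known array design; the
    grid is never inferred from the image. Area bounds and the closing
    radius default to values derived from the design spacing (image
    extent divided by the grid), making them resolution-independent:
    expected core radius ~ 0.8 * spacing / 2, with the area window
    [0.2, 2.5] * pi * r^2.
    """

    grid_rows: int
    grid_cols: int
    min_area: float | None = None
    max_area: float | None = None
    struct_radius: int | None = None
    col_tolerance: float = 0.35  # fraction of spacing, perpendicular offset
    spacing_window: tuple[float, float] = (0.5, 1.5)  # multiples of k*spacing
    max_gap: int | None = None  # default: grid dimension - 1
    baseline_min_fraction: float = 0.5
    invert_labels: bool = True

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if not (0 < self.col_tolerance < 1):
            raise ValueError("col_tolerance must be in (0, 1)")
        lo, hi = self.spacing_window
        if not lo < hi:
            raise ValueError("spacing_window must satisfy low < high")

    def design_spacing(self, thumb_shape) -> float:
        """Nominal core spacing implied by image extent and grid design."""
        h, w = thumb_shape[:2]
        return min(h / (self.grid_rows + 1), w / (self.grid_cols + 1))

    def area_bounds(self, thumb_shape) -> tuple[float, float]:
        if self.min_area is not None and self.max_area is not None:
            return self.min_area, self.max_area
        r = 0.8 * self.design_spacing(thumb_shape) / 2.0
        disk = math.pi * r * r
        lo = self.min_area if self.min_area is not None else 0.2 * disk
        hi = self.max_area if self.max_area is not None else 2.5 * disk
        return lo, hi


@dataclass
class CoreRecord:
    """One gridded, scored TMA core."""

    row: int  # 1-based grid row
    col: int  # 1-based grid col
    centroid_full_x: int
    centroid_full_y: int
    gleason: int | None = None
    quant: StainQuant | None = None


# ---------------------------------------------------------------------------
# detection


def detect_cores(
    thumb,
    params: PixelClassParams = PixelClassParams(),
    dp: DearrayParams | None = None,
) -> list[CoreBlob]:
    """Detect TMA cores on a thumbnail image.

    Foreground is everything the pixel rules call tissue. Closing with a
    disk of ``struct_radius`` merges fragments; hole filling solidifies
    cores; components with area outside the window are discarded.
    """
    if dp is None:
        raise ValueError("DearrayParams (with the TMA grid design) are required")
    fg = ~background_mask(thumb, params)
    spacing = dp.design_spacing(np.asarray(thumb).shape)
    radius = dp.struct_radius if dp.struct_radius is not None else max(3, round(0.05 * spacing))
    closed = morphology.closing(fg, morphology.disk(radius))
    filled = ndimage.binary_fill_holes(closed)
    labeled = measure.label(filled)
    props = measure.regionprops(labeled)
    lo, hi = dp.area_bounds(np.asarray(thumb).shape)
    blobs = [
        CoreBlob(centroid_x=p.centroid[1], centroid_y=p.centroid[0], area=int(p.area))
        for p in props
        if lo <= p.area <= hi
    ]
    if not blobs:
        areas = sorted(int(p.area) for p in props)
        raise ValueError(
            f"no cores detected: {len(props)} components, all outside area "
            f"window [{lo:.0f}, {hi:.0f}]; component areas: {areas[:20]}"
        )
    return blobs


def build_centroid_table(blobs: list[CoreBlob]) -> pd.DataFrame:
    """Centroid table: x, y, their sum, and (to be filled) grid labels."""
    df = pd.DataFrame(
        {
            "centroid_x": [b.centroid_x for b in blobs],
            "centroid_y": [b.centroid_y for b in blobs],
        }
    )
    df["coord_sum"] = df["centroid_x"] + df["centroid_y"]
    df["assigned_row"] = EMPTY
    df["assigned_col"] = EMPTY
    return df


# ---------------------------------------------------------------------------
# gridding


def find_origin_core(table: pd.DataFrame) -> int:
    """Index of the core nearest the top-left image origin.

    Minimal ``x + y``; ties broken by smaller y, then smaller x.
    """
    if len(table) == 0:
        raise ValueError("empty centroid table")
    order = table.sort_values(
        ["coord_sum", "centroid_y", "centroid_x"], kind="mergesort"
    )
    return int(order.index[0])


def estimate_spacing(table: pd.DataFrame) -> float:
    """Median nearest-neighbor distance among core centroids."""
    pts = table[["centroid_x", "centroid_y"]].to_numpy(float)
    if len(pts) < 2:
        raise ValueError("need at least two centroids to estimate spacing")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    return float(np.median(d[:, 1]))


def _walk_line(
    table: pd.DataFrame,
    start_idx: int,
    axis: str,
    spacing: float,
    dp: DearrayParams,
    n_cells: int,
    used: set[int],
) -> dict[int, int]:
    """Walk from a start core along one grid line, bridging gaps.

    ``axis`` is "y" to walk down a column (vertical progress, horizontal
    tolerance) or "x" to walk along a row. Returns ``{cell_index ->
    table_index}`` with the start core at cell 0.
    """
    along = "centroid_y" if axis == "y" else "centroid_x"
    across = "centroid_x" if axis == "y" else "centroid_y"
    max_gap = dp.max_gap if dp.max_gap is not None else n_cells - 1
    lo_f, hi_f = dp.spacing_window

    assigned = {0: start_idx}
    cur_idx = start_idx
    cur_cell = 0
    while cur_cell < n_cells - 1:
        cur_along = table.at[cur_idx, along]
        cur_across = table.at[cur_idx, across]
        hit = None
        for k in range(1, max_gap + 1):
            if cur_cell + k > n_cells - 1:
                break
            lo, hi = lo_f * k * spacing, hi_f * k * spacing
            best, best_d = None, np.inf
            for idx in table.index:
                if idx in used or idx in assigned.values():
                    continue
                d_along = table.at[idx, along] - cur_along
                d_across = abs(table.at[idx, across] - cur_across)
                if d_across > dp.col_tolerance * spacing:
                    continue
                if not (lo <= d_along <= hi):
                    continue
                # nearest to the predicted lattice position
                pred = cur_along + k * spacing
                dist = math.hypot(table.at[idx, along] - pred, d_across)
                if dist < best_d:
                    best, best_d = idx, dist
            if best is not None:
                hit = (k, best)
                break
        if hit is None:
            break
        k, idx = hit
        # the search windows for k >= 2 overlap; the actual lattice step
        # is the measured offset in units of the spacing
        d_along = table.at[idx, along] - table.at[cur_idx, along]
        step = int(np.clip(round(d_along / spacing), 1, n_cells - 1 - cur_cell))
        cur_cell += step
        assigned[cur_cell] = idx
        cur_idx = idx
    return assigned


def assemble_grid(table: pd.DataFrame, dp: DearrayParams) -> np.ndarray:
    """Assign every detected core a grid cell; return the location matrix.

    The matrix has shape ``(grid_rows, grid_cols)``; each cell holds the
    centroid-table index of its core or the ``EMPTY`` marker. The table's
    ``assigned_row``/``assigned_col`` columns are filled in place
    (0-based; callers present 1-based labels).
    """
    if len(table) == 0:
        raise ValueError("empty centroid table")
    matrix = np.full((dp.grid_rows, dp.grid_cols), EMPTY, dtype=int)
    if len(table) == 1:
        matrix[0, 0] = int(table.index[0])
        _write_assignments(table, matrix)
        return matrix

    spacing = estimate_spacing(table)
    origin = find_origin_core(table)
    used: set[int] = set()

    # baseline: first column, else first row
    col_walk = _walk_line(table, origin, "y", spacing, dp, dp.grid_rows, used)
    if len(col_walk) >= dp.baseline_min_fraction * dp.grid_rows:
        baseline_axis = "y"
        baseline = col_walk
    else:
        row_walk = _walk_line(table, origin, "x", spacing, dp, dp.grid_cols, used)
        if len(row_walk) < dp.baseline_min_fraction * dp.grid_cols:
            raise ValueError(
                "gridding failed: neither the first column nor the first row "
                f"yields a valid baseline; detected centroids:\n{table[['centroid_x', 'centroid_y']]}"
            )
        baseline_axis = "x"
        baseline = row_walk

    if baseline_axis == "y":
        for r, idx in baseline.items():
            matrix[r, 0] = idx
            used.add(idx)
        for r in range(dp.grid_rows):
            if matrix[r, 0] == EMPTY:
                continue
            line = _walk_line(table, int(matrix[r, 0]), "x", spacing, dp, dp.grid_cols, used)
            for c, idx in line.items():
                if matrix[r, c] == EMPTY:
                    matrix[r, c] = idx
                    used.add(idx)
    else:
        for c, idx in baseline.items():
            matrix[0, c] = idx
            used.add(idx)
        for c in range(dp.grid_cols):
            if matrix[0, c] == EMPTY:
                continue
            line = _walk_line(table, int(matrix[0, c]), "y", spacing, dp, dp.grid_rows, used)
            for r, idx in line.items():
                if matrix[r, c] == EMPTY:
                    matrix[r, c] = idx
                    used.add(idx)

    matrix = _register_grid(table, matrix, spacing, dp)
    _reconcile_unassigned(table, matrix, spacing, dp)
    _write_assignments(table, matrix)
    return matrix


def _register_grid(
    table: pd.DataFrame, matrix: np.ndarray, spacing: float, dp: DearrayParams
) -> np.ndarray:
    """Shift the walked assignment onto the absolute design lattice.

    The walk anchors at the detected origin core, which occupies design
    cell (0, 0) only when the top-left corner of the array is actually
    present. Each centroid's absolute lattice index is estimated
    independently as its offset from the extreme centroid coordinate in
    units of the spacing; the matrix is shifted by the modal difference
    between estimated and walked indices.
    """
    x = table["centroid_x"].to_numpy(float)
    y = table["centroid_y"].to_numpy(float)
    r_est = np.round((y - y.min()) / spacing).astype(int)
    c_est = np.round((x - x.min()) / spacing).astype(int)
    dr_votes, dc_votes = [], []
    for r in range(dp.grid_rows):
        for c in range(dp.grid_cols):
            idx = matrix[r, c]
            if idx == EMPTY:
                continue
            pos = table.index.get_loc(int(idx))
            dr_votes.append(r_est[pos] - r)
            dc_votes.append(c_est[pos] - c)
    if not dr_votes:
        return matrix
    dr = int(np.bincount(np.array(dr_votes) - min(dr_votes)).argmax()) + min(dr_votes)
    dc = int(np.bincount(np.array(dc_votes) - min(dc_votes)).argmax()) + min(dc_votes)
    if dr == 0 and dc == 0:
        return matrix
    shifted = np.full_like(matrix, EMPTY)
    for r in range(dp.grid_rows):
        for c in range(dp.grid_cols):
            idx = matrix[r, c]
            if idx == EMPTY:
                continue
            nr, nc = r + dr, c + dc
            if 0 <= nr < dp.grid_rows and 0 <= nc < dp.grid_cols:
                shifted[nr, nc] = idx
            else:
                log.warning(
                    "core %d shifted off the declared grid during registration", idx
                )
    return shifted


def _reconcile_unassigned(
    table: pd.DataFrame, matrix: np.ndarray, spacing: float, dp: DearrayParams
) -> None:
    """Place centroids the walks missed into predicted empty cells.

    Row y-coordinates and column x-coordinates are estimated from the
    assigned cores (median per line, linearly extrapolated by the
    spacing for lines with no member yet); a leftover centroid joins the
    nearest empty cell if both offsets are within ``col_tolerance *
    spacing``.
    """
    assigned = set(int(i) for i in matrix.ravel() if i != EMPTY)
    leftovers = [int(i) for i in table.index if int(i) not in assigned]
    if not leftovers:
        return

    def line_coords(n: int, axis: int, coord: str) -> np.ndarray:
        # axis 0 -> rows use centroid_y; axis 1 -> cols use centroid_x
        est = np.full(n, np.nan)
        for i in range(n):
            members = matrix[i, :] if axis == 0 else matrix[:, i]
            vals = [table.at[int(m), coord] for m in members if m != EMPTY]
            if vals:
                est[i] = float(np.median(vals))
        known = np.flatnonzero(~np.isnan(est))
        if known.size == 0:
            return est
        for i in range(n):
            if np.isnan(est[i]):
                j = known[np.argmin(np.abs(known - i))]
                est[i] = est[j] + (i - j) * spacing
        return est

    row_y = line_coords(dp.grid_rows, 0, "centroid_y")
    col_x = line_coords(dp.grid_cols, 1, "centroid_x")
    tol = dp.col_tolerance * spacing
    for idx in leftovers:
        x, y = table.at[idx, "centroid_x"], table.at[idx, "centroid_y"]
        best, best_d = None, np.inf
        for r in range(dp.grid_rows):
            for c in range(dp.grid_cols):
                if matrix[r, c] != EMPTY:
                    continue
                dx, dy = abs(x - col_x[c]), abs(y - row_y[r])
                if dx > tol or dy > tol:
                    continue
                d = math.hypot(dx, dy)
                if d < best_d:
                    best, best_d = (r, c), d
        if best is None:
            log.warning(
                "core at (%.1f, %.1f) could not be placed in any grid cell", x, y
            )
            continue
        matrix[best] = idx


def _write_assignments(table: pd.DataFrame, matrix: np.ndarray) -> None:
    table["assigned_row"] = EMPTY
    table["assigned_col"] = EMPTY
    rows, cols = np.nonzero(matrix != EMPTY)
    for r, c in zip(rows, cols):
        idx = int(matrix[r, c])
        table.at[idx, "assigned_row"] = int(r)
        table.at[idx, "assigned_col"] = int(c)


def invert_grid_labels(matrix: np.ndarray) -> np.ndarray:
    """Reverse both grid axes: row r -> last+1-r, col c -> last+1-c.

    TMA scans are commonly oriented opposite to the pathologist's
    numbering; flipping both axes restores the conventional labels.
    Involution: applying twice restores the original.
    """
    return matrix[::-1, ::-1].copy()


# ---------------------------------------------------------------------------
# full-resolution scoring


def scale_centroids(table: pd.DataFrame, thumb_shape, full_shape) -> pd.DataFrame:
    """Map thumbnail centroids to full-resolution pixel coordinates.

    Per-axis scale factors; results rounded to the nearest pixel
    (ties to even). The two images must depict the same scene: aspect
    ratios must agree within 1%.
    """
    th, tw = thumb_shape[:2]
    fh, fw = full_shape[:2]
    if abs((fw / fh) / (tw / th) - 1) > 0.01:
        raise ValueError(
            f"aspect-ratio mismatch: thumbnail {tw}x{th} vs full {fw}x{fh}"
        )
    out = table.copy()
    out["centroid_full_x"] = np.round(table["centroid_x"] * (fw / tw)).astype(int)
    out["centroid_full_y"] = np.round(table["centroid_y"] * (fh / th)).astype(int)
    return out


def score_core(
    full,
    centroid_full_x: int,
    centroid_full_y: int,
    window_side: int,
    params: PixelClassParams = PixelClassParams(),
) -> StainQuant:
    """Quantify stain in a square window around one core centroid.

    The window defaults (at the caller) to the estimated spacing scaled
    to full resolution, so neighboring windows abut without overlapping.
    Windows are clipped to the image bounds; a window containing no
    tissue yields ``sample_pixels == 0`` with an undefined fraction.
    """
    arr = np.asarray(full) if not hasattr(full, "shape") else full
    h, w = arr.shape[:2]
    half = window_side // 2
    r0 = max(0, int(centroid_full_y) - half)
    r1 = min(h, int(centroid_full_y) + half + 1)
    c0 = max(0, int(centroid_full_x) - half)
    c1 = min(w, int(centroid_full_x) + half + 1)
    window = np.asarray(arr[r0:r1, c0:c1])
    _, quant = classify_image(window, params)
    if quant.sample_pixels == 0:
        log.warning(
            "core window at (%d, %d) contains no sample tissue",
            centroid_full_x,
            centroid_full_y,
        )
    return quant


# ---------------------------------------------------------------------------
# annotations and export


def join_annotations(records: list[CoreRecord], annot: pd.DataFrame) -> list[CoreRecord]:
    """Attach pathologist Gleason scores to cores, matched on (row, col).

    The annotation table needs columns ``row``, ``col``, ``gleason``
    (1-based grid labels). Unmatched cores keep a missing score with a
    warning; annotation rows matching no detected core are logged.
    """
    required = {"row", "col", "gleason"}
    if not required.issubset(annot.columns):
        raise ValueError(f"annotation table must have columns {sorted(required)}")
    keys = list(zip(annot["row"].astype(int), annot["col"].astype(int)))
    if len(keys) != len(set(keys)):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate (row, col) in annotation table: {dupes}")
    lookup = {k: g for k, g in zip(keys, annot["gleason"])}
    matched = set()
    for rec in records:
        key = (rec.row, rec.col)
        if key in lookup:
            rec.gleason = int(lookup[key])
            matched.add(key)
        else:
            log.warning("core at grid (%d, %d) has no annotation", rec.row, rec.col)
    for key in lookup:
        if key not in matched:
            log.warning("annotation for grid %s matches no detected core", key)
    return records


def export_results(records: list[CoreRecord], path) -> pd.DataFrame:
    """Write the per-core results table (CSV; .xlsx if so named).

    Columns: centroid_x, centroid_y, row, col, gleason, percent_stained
    (100 * stain fraction; left empty — never 0 — when the core window
    held no tissue). Rows in row-major grid order.
    """
    recs = sorted(records, key=lambda r: (r.row, r.col))
    rows = []
    for r in recs:
        frac = r.quant.stain_fraction if r.quant is not None else None
        rows.append(
            {
                "centroid_x": r.centroid_full_x,
                "centroid_y": r.centroid_full_y,
                "row": r.row,
                "col": r.col,
                "gleason": r.gleason if r.gleason is not None else pd.NA,
                "percent_stained": 100 * frac if frac is not None else pd.NA,
            }
        )
    df = pd.DataFrame(rows)
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)
    return df


# ---------------------------------------------------------------------------
# orchestration


def dearray(
    thumb,
    full,
    dp: DearrayParams,
    params: PixelClassParams = PixelClassParams(),
    annotations: pd.DataFrame | None = None,
    window_side: int | None = None,
) -> list[CoreRecord]:
    """Run the complete TMA workflow and return scored core records."""
    blobs = detect_cores(thumb, params, dp)
    table = build_centroid_table(blobs)
    matrix = assemble_grid(table, dp)
    if dp.invert_labels:
        matrix = invert_grid_labels(matrix)
    thumb_shape = np.asarray(thumb).shape
    full_shape = full.shape if hasattr(full, "shape") else np.asarray(full).shape
    table = scale_centroids(table, thumb_shape, full_shape)
    if window_side is None:
        spacing = estimate_spacing(table) if len(table) > 1 else dp.design_spacing(thumb_shape)
        scale = full_shape[1] / thumb_shape[1]
        window_side = int(round(spacing * scale))
    records = []
    for r in range(dp.grid_rows):
        for c in range(dp.grid_cols):
            idx = matrix[r, c]
            if idx == EMPTY:
                continue
            cx = int(table.at[int(idx), "centroid_full_x"])
            cy = int(table.at[int(idx), "centroid_full_y"])
            quant = score_core(full, cx, cy, window_side, params)
            records.append(
                CoreRecord(row=r + 1, col=c + 1, centroid_full_x=cx, centroid_full_y=cy, quant=quant)
            )
    if annotations is not None:
        join_annotations(records, annotations)
    return records
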