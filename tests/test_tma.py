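"""TMA de-arraying tests: detection, gridding, scaling, scoring, export."""

import numpy as np
import pandas as pd
import pytest

from ihcquant.pixels import PixelLabel
from ihcquant.quant import StainQuant
from ihcquant.synthetic import TMALayoutSpec, gen_tma_image, sample_colors
from ihcquant.tma import (
    EMPTY,
    CoreRecord,
    DearrayParams,
    assemble_grid,
    build_centroid_table,
    dearray,
    detect_cores,
    estimate_spacing,
    export_results,
    find_origin_core,
    invert_grid_labels,
    join_annotations,
    scale_centroids,
    score_core,
)


def draw_core(img, cx, cy, radius, rng, gap_cols=0):
    """Paint an unstained circular core; optionally split by a column gap."""
    h, w, _ = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    if gap_cols:
        disk &= np.abs(xx - cx) > gap_cols // 2
    idx = np.flatnonzero(disk.ravel())
    img.reshape(-1, 3)[idx] = sample_colors(PixelLabel.SAMPLE_UNSTAINED, idx.size, rng)
    return disk


class TestDetectCores:
    def test_clean_grid_nine_blobs(self, tma_clean):
        thumb, _, truth, spec = tma_clean
        dp = DearrayParams(3, 3)
        blobs = detect_cores(thumb, dp=dp)
        assert len(blobs) == 9
        found = {(round(b.centroid_x), round(b.centroid_y)) for b in blobs}
        for _, row in truth.iterrows():
            assert any(
                abs(fx - row.centroid_x) <= 2 and abs(fy - row.centroid_y) <= 2
                for fx, fy in found
            )

    def test_fragmented_core_merged_by_closing(self):
        rng = np.random.default_rng(0)
        img = np.full((120, 120, 3), 250, dtype=np.uint8)
        draw_core(img, 60, 60, 25, rng, gap_cols=3)
        dp = DearrayParams(1, 1, min_area=500, max_area=5000, struct_radius=3)
        blobs = detect_cores(img, dp=dp)
        assert len(blobs) == 1
        assert abs(blobs[0].centroid_x - 60) < 3 and abs(blobs[0].centroid_y - 60) < 3

    def test_merged_pair_removed_other_cores_kept(self):
        rng = np.random.default_rng(1)
        img = np.full((150, 300, 3), 250, dtype=np.uint8)
        # two overlapping cores form one oversized object
        draw_core(img, 80, 75, 30, rng)
        draw_core(img, 120, 75, 30, rng)
        # one normal core elsewhere
        draw_core(img, 230, 75, 30, rng)
        single_area = np.pi * 30**2
        dp = DearrayParams(1, 3, min_area=0.5 * single_area, max_area=1.5 * single_area)
        blobs = detect_cores(img, dp=dp)
        assert len(blobs) == 1
        assert abs(blobs[0].centroid_x - 230) < 3

    def test_empty_slide_raises(self):
        img = np.full((200, 200, 3), 250, dtype=np.uint8)
        with pytest.raises(ValueError, match="no cores"):
            detect_cores(img, dp=DearrayParams(2, 2))

    def test_debris_filtered_out(self):
        spec = TMALayoutSpec(grid_rows=2, grid_cols=2, spacing=100,
                             core_radius=30, debris_count=10, seed=4)
        thumb, _, _ = gen_tma_image(spec)
        blobs = detect_cores(thumb, dp=DearrayParams(2, 2))
        assert len(blobs) == 4


class TestOriginAndSpacing:
    def test_unique_minimal_sum(self):
        table = build_centroid_table_from([(10, 10), (10, 50), (50, 10)])
        idx = find_origin_core(table)
        assert (table.at[idx, "centroid_x"], table.at[idx, "centroid_y"]) == (10, 10)

    def test_tie_broken_by_y_then_x(self):
        table = build_centroid_table_from([(0, 40), (40, 0)])
        idx = find_origin_core(table)
        assert (table.at[idx, "centroid_x"], table.at[idx, "centroid_y"]) == (40, 0)

    def test_single_centroid(self):
        table = build_centroid_table_from([(7, 9)])
        assert find_origin_core(table) == table.index[0]

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            find_origin_core(build_centroid_table_from([]))

    def test_spacing_is_median_nearest_neighbor(self):
        pts = [(x * 100, y * 100) for x in range(3) for y in range(3)]
        assert estimate_spacing(build_centroid_table_from(pts)) == pytest.approx(100)


def build_centroid_table_from(points):
    df = pd.DataFrame(points, columns=["centroid_x", "centroid_y"], dtype=float)
    df["coord_sum"] = df["centroid_x"] + df["centroid_y"]
    df["assigned_row"] = EMPTY
    df["assigned_col"] = EMPTY
    return df


class TestAssembleGrid:
    def test_perfect_grid_identity_assignment(self):
        pts = [(50 + 100 * c, 50 + 100 * r) for r in range(3) for c in range(3)]
        table = build_centroid_table_from(pts)
        m = assemble_grid(table, DearrayParams(3, 3))
        for r in range(3):
            for c in range(3):
                idx = int(m[r, c])
                assert table.at[idx, "centroid_x"] == 50 + 100 * c
                assert table.at[idx, "centroid_y"] == 50 + 100 * r

    def test_missing_center_bridged_by_expanded_search(self):
        pts = [
            (50 + 100 * c, 50 + 100 * r)
            for r in range(3)
            for c in range(3)
            if not (r == 1 and c == 1)
        ]
        table = build_centroid_table_from(pts)
        m = assemble_grid(table, DearrayParams(3, 3))
        assert m[1, 1] == EMPTY
        assert (m != EMPTY).sum() == 8

    def test_injectivity_no_core_in_two_cells(self):
        spec = TMALayoutSpec(grid_rows=4, grid_cols=4, spacing=80, core_radius=25,
                             jitter_fraction=0.08, missing_prob=0.15, seed=13)
        thumb, _, _ = gen_tma_image(spec)
        dp = DearrayParams(4, 4, invert_labels=False)
        table = build_centroid_table(detect_cores(thumb, dp=dp))
        m = assemble_grid(table, dp)
        assigned = [int(i) for i in m.ravel() if i != EMPTY]
        assert len(assigned) == len(set(assigned)) == len(table)

    def test_recovery_under_jitter_and_missing(self):
        """All surviving cores get their ground-truth cell: 5x5, 10% jitter,
        20% missing, 10 seeds."""
        for seed in range(10):
            spec = TMALayoutSpec(grid_rows=5, grid_cols=5, spacing=100,
                                 core_radius=30, jitter_fraction=0.10,
                                 missing_prob=0.2, seed=seed)
            thumb, _, truth = gen_tma_image(spec)
            dp = DearrayParams(5, 5, invert_labels=False)
            table = build_centroid_table(detect_cores(thumb, dp=dp))
            m = assemble_grid(table, dp)
            for _, row in truth[truth.present].iterrows():
                idx = m[row.row - 1, row.col - 1]
                assert idx != EMPTY, f"seed {seed}: cell ({row.row},{row.col}) empty"
                assert abs(table.at[int(idx), "centroid_x"] - row.centroid_x) < 5
                assert abs(table.at[int(idx), "centroid_y"] - row.centroid_y) < 5


class TestInvertLabels:
    def test_first_row_becomes_last(self):
        m = np.arange(12).reshape(4, 3)
        inv = invert_grid_labels(m)
        assert (inv[3] == m[0][::-1]).all()

    def test_involution(self):
        m = np.arange(20).reshape(4, 5)
        assert (invert_grid_labels(invert_grid_labels(m)) == m).all()

    def test_one_by_one_unchanged(self):
        m = np.array([[3]])
        assert (invert_grid_labels(m) == m).all()


class TestScaleCentroids:
    def test_factor_four(self):
        table = build_centroid_table_from([(100, 200)])
        out = scale_centroids(table, (800, 1000), (3200, 4000))
        assert (out.at[out.index[0], "centroid_full_x"],
                out.at[out.index[0], "centroid_full_y"]) == (400, 800)

    def test_identity_factor(self):
        table = build_centroid_table_from([(33, 17)])
        out = scale_centroids(table, (100, 100), (100, 100))
        assert out.at[out.index[0], "centroid_full_x"] == 33

    def test_round_half_even(self):
        table = build_centroid_table_from([(33, 17)])
        out = scale_centroids(table, (100, 100), (250, 250))
        # 33*2.5 = 82.5 -> 82; 17*2.5 = 42.5 -> 42 (ties to even)
        assert out.at[out.index[0], "centroid_full_x"] == 82
        assert out.at[out.index[0], "centroid_full_y"] == 42

    def test_aspect_ratio_mismatch_raises(self):
        table = build_centroid_table_from([(10, 10)])
        with pytest.raises(ValueError, match="aspect"):
            scale_centroids(table, (100, 100), (400, 300))


class TestScoreCore:
    def test_known_core_fraction(self, tma_clean):
        thumb, full, truth, spec = tma_clean
        row = truth.iloc[0]
        f = spec.upscale
        q = score_core(full, row.centroid_x * f, row.centroid_y * f,
                       window_side=spec.spacing * f)
        assert q.stain_fraction == pytest.approx(row.stain_fraction, abs=1e-9)

    def test_empty_window_undefined(self):
        img = np.full((100, 100, 3), 250, dtype=np.uint8)
        q = score_core(img, 50, 50, window_side=40)
        assert q.sample_pixels == 0 and q.stain_fraction is None

    def test_edge_core_clipped_conserves(self):
        rng = np.random.default_rng(2)
        img = np.full((100, 100, 3), 250, dtype=np.uint8)
        draw_core(img, 5, 50, 20, rng)
        q = score_core(img, 5, 50, window_side=60)
        assert q.background_pixels + q.sample_pixels == q.total_pixels
        assert q.total_pixels < 61 * 61  # clipped at the left edge
        assert q.sample_pixels > 0


def make_record(row, col, frac=0.5):
    n = 100
    stained = int(frac * n)
    return CoreRecord(
        row=row, col=col, centroid_full_x=10 * col, centroid_full_y=10 * row,
        quant=StainQuant(2 * n, n, n, stained, n - stained),
    )


class TestAnnotationsAndExport:
    def test_exact_join(self):
        recs = [make_record(2, 3)]
        annot = pd.DataFrame({"row": [2], "col": [3], "gleason": [7]})
        assert join_annotations(recs, annot)[0].gleason == 7

    def test_unmatched_record_keeps_missing(self, caplog):
        recs = [make_record(1, 1)]
        annot = pd.DataFrame({"row": [2], "col": [2], "gleason": [6]})
        out = join_annotations(recs, annot)
        assert out[0].gleason is None

    def test_duplicate_annotation_raises(self):
        annot = pd.DataFrame({"row": [1, 1], "col": [2, 2], "gleason": [6, 7]})
        with pytest.raises(ValueError, match="duplicate"):
            join_annotations([make_record(1, 2)], annot)

    def test_export_round_trip(self, tmp_path):
        recs = [make_record(r, c) for r in range(1, 4) for c in range(1, 4)]
        path = tmp_path / "cores.csv"
        df = export_results(recs, path)
        assert len(df) == 9
        back = pd.read_csv(path)
        assert (back[["row", "col"]].values == df[["row", "col"]].values).all()
        assert back["percent_stained"].tolist() == pytest.approx([50.0] * 9)

    def test_undefined_fraction_exports_empty_cell(self, tmp_path):
        rec = CoreRecord(row=1, col=1, centroid_full_x=5, centroid_full_y=5,
                         quant=StainQuant(100, 100, 0, 0, 0))
        path = tmp_path / "cores.csv"
        export_results([rec], path)
        back = pd.read_csv(path)
        assert back["percent_stained"].isna().all()


class TestEndToEnd:
    def test_dearray_scores_and_joins(self, tma_clean):
        thumb, full, truth, spec = tma_clean
        annot = truth[["row", "col"]].copy()
        annot["gleason"] = [6, 7, 8, 9, 6, 7, 8, 9, 6]
        dp = DearrayParams(3, 3, invert_labels=False)
        records = dearray(thumb, full, dp, annotations=annot)
        assert len(records) == 9
        by_cell = {(r.row, r.col): r for r in records}
        for _, row in truth.iterrows():
            rec = by_cell[(row.row, row.col)]
            assert rec.quant.stain_fraction == pytest.approx(row.stain_fraction, abs=0.02)
            expected_g = int(annot[(annot.row == row.row) & (annot.col == row.col)].gleason.iloc[0])
            assert rec.gleason == expected_g

    def test_inversion_flips_reported_cells(self, tma_clean):
        thumb, full, truth, _ = tma_clean
        plain = dearray(thumb, full, DearrayParams(3, 3, invert_labels=False))
        flipped = dearray(thumb, full, DearrayParams(3, 3, invert_labels=True))
        plain_map = {(r.row, r.col): r.centroid_full_x for r in plain}
        for r in flipped:
            assert plain_map[(4 - r.row, 4 - r.col)] == r.centroid_full_x
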