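"""Tissue masking, tiling, and patch gating."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.measure import label as cc_label

from evoslide.preprocess import (
    MaskFractionScorer,
    PatchRecord,
    TissueMask,
    export_annotated_thumbnail,
    patch_filter,
    score_patches,
    tile_positions,
    tissue_mask,
)
from evoslide.synthetic import SyntheticSlideSpec, gen_slide


def _textured_region(region_mask, seed=0):
    """Render a synthetic slide texture inside an arbitrary pixel region."""
    spec = SyntheticSlideSpec(grid_rows=region_mask.shape[0] // 32,
                              grid_cols=region_mask.shape[1] // 32,
                              class_label=0, seed=seed)
    full = gen_slide(spec).thumbnail
    img = np.full(region_mask.shape, 230, dtype=np.uint8)
    img[region_mask] = full[region_mask]
    return img


class TestTissueMask:
    def test_uniform_image_gives_empty_mask(self):
        mask = tissue_mask(np.full((64, 64), 128, dtype=np.uint8))
        assert not mask.mask.any()

    def test_textured_disk_recovered_with_high_iou(self):
        yy, xx = np.mgrid[0:256, 0:256]
        disk_gt = (yy - 128) ** 2 + (xx - 128) ** 2 <= 80 ** 2
        img = _textured_region(disk_gt, seed=1)
        m = tissue_mask(img).mask
        iou = (m & disk_gt).sum() / (m | disk_gt).sum()
        assert iou >= 0.9

    def test_two_blobs_give_two_components(self):
        yy, xx = np.mgrid[0:256, 0:256]
        blobs = ((yy - 64) ** 2 + (xx - 64) ** 2 <= 40 ** 2) | (
            (yy - 192) ** 2 + (xx - 192) ** 2 <= 40 ** 2
        )
        img = _textured_region(blobs, seed=2)
        m = tissue_mask(img).mask
        assert cc_label(m).max() == 2

    def test_hole_filling_is_idempotent(self):
        from scipy.ndimage import binary_fill_holes

        yy, xx = np.mgrid[0:256, 0:256]
        disk_gt = (yy - 128) ** 2 + (xx - 128) ** 2 <= 80 ** 2
        m = tissue_mask(_textured_region(disk_gt, seed=3)).mask
        np.testing.assert_array_equal(binary_fill_holes(m), m)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            tissue_mask(np.zeros((16, 16)))


class TestTilePositions:
    def test_exact_tiling(self):
        assert len(tile_positions(1000, 1000, 250, 250)) == 16

    def test_overlapping_stride(self):
        # floor((1000 - 250)/125) + 1 = 7 positions per axis
        assert len(tile_positions(1000, 1000, 250, 125)) == 49

    def test_oversized_patch_gives_empty(self):
        assert tile_positions(1000, 1000, 2000, 250) == []

    def test_row_major_half_open(self):
        boxes = tile_positions(64, 64, 32, 32)
        assert boxes == [(0, 0, 32, 32), (32, 0, 64, 32),
                         (0, 32, 32, 64), (32, 32, 64, 64)]

    def test_exact_stride_covers_without_overlap(self):
        boxes = tile_positions(96, 64, 32, 32)
        covered = np.zeros((64, 96), dtype=int)
        for x0, y0, x1, y1 in boxes:
            covered[y0:y1, x0:x1] += 1
        assert (covered == 1).all()


def _grid_mask_and_records(scores_by_row):
    """4x4 grid of 32 px patches; left two columns are tissue."""
    mask = np.zeros((128, 128), dtype=bool)
    mask[:, :64] = True
    boxes = tile_positions(128, 128, 32, 32)
    records = [PatchRecord("s", b) for b in boxes]

    def scorer(rec):
        row = rec.box[1] // 32
        return scores_by_row.get(row, 0.0)

    return TissueMask(mask=mask), records, scorer


class TestPatchFilter:
    def test_constructed_grid_retains_exactly_two(self):
        mask, records, scorer = _grid_mask_and_records({0: 0.9})
        retained = patch_filter(records, mask, scorer)
        assert len(retained) == 2
        assert all(r.box[1] == 0 and r.box[0] < 64 for r in retained)

    def test_boundary_tissue_fraction_dropped(self):
        # a patch with exactly 10% tissue must not be retained
        mask = np.zeros((32, 32), dtype=bool)
        mask[:, :16] = True
        rec = PatchRecord("s", (0, 0, 32, 10))  # 10 of 100 rows? use exact frac
        mask = np.zeros((100, 100), dtype=bool)
        mask[0:10, 0:100] = True  # exactly 10% of the 100x100 box
        rec = PatchRecord("s", (0, 0, 100, 100))
        out = score_patches([rec], TissueMask(mask=mask), lambda r: 1.0)
        assert out[0].tissue_fraction == pytest.approx(0.10)
        assert not out[0].retained

    def test_boundary_tumor_probability_dropped(self):
        mask = np.ones((32, 32), dtype=bool)
        rec = PatchRecord("s", (0, 0, 32, 32))
        out = score_patches([rec], TissueMask(mask=mask), lambda r: 0.50)
        assert not out[0].retained
        out = score_patches([rec], TissueMask(mask=mask), lambda r: 0.51)
        assert out[0].retained

    def test_scorer_out_of_range_rejected(self):
        mask = np.ones((32, 32), dtype=bool)
        rec = PatchRecord("s", (0, 0, 32, 32))
        with pytest.raises(ValueError, match="outside"):
            score_patches([rec], TissueMask(mask=mask), lambda r: 1.5)

    def test_mask_fraction_scorer_is_box_mean(self):
        tumor = np.zeros((64, 64), dtype=bool)
        tumor[0:32, 0:16] = True
        scorer = MaskFractionScorer(tumor)
        assert scorer(PatchRecord("s", (0, 0, 32, 32))) == pytest.approx(0.5)
        assert scorer(PatchRecord("s", (32, 32, 64, 64))) == 0.0

    @given(st.floats(0.1, 0.9), st.floats(0.5, 0.95))
    @settings(max_examples=20, deadline=None)
    def test_retention_monotone_in_thresholds(self, t_tissue, t_tumor):
        mask, records, scorer = _grid_mask_and_records({0: 0.9, 1: 0.6})
        base = {r.box for r in patch_filter(records, mask, scorer)}
        stricter = {
            r.box
            for r in patch_filter(records, mask, scorer,
                                  tissue_threshold=t_tissue,
                                  tumor_threshold=t_tumor)
        }
        assert stricter <= base


class TestAnnotatedThumbnail:
    def test_no_records_leaves_image_unchanged(self):
        img = np.full((64, 64), 100, dtype=np.uint8)
        out = export_annotated_thumbnail(img, [], path=None)
        np.testing.assert_array_equal(out, np.stack([img] * 3, axis=2))

    def test_two_rectangles_drawn(self):
        img = np.zeros((64, 64), dtype=np.uint8)
        recs = [PatchRecord("s", (0, 0, 16, 16)), PatchRecord("s", (32, 32, 48, 48))]
        out = export_annotated_thumbnail(img, recs, path=None)
        red = (out[..., 0] == 255) & (out[..., 1] == 0)
        # each 16x16 outline = 4*16 - 4 = 60 pixels
        assert red.sum() == 120
        assert cc_label(red).max() == 2

    def test_out_of_bounds_clipped(self, tmp_path):
        img = np.zeros((32, 32), dtype=np.uint8)
        recs = [PatchRecord("s", (16, 16, 64, 64))]
        out = export_annotated_thumbnail(img, recs, path=tmp_path / "a.png")
        assert (out[..., 0] == 255).any()
        assert (tmp_path / "a.png").exists()
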