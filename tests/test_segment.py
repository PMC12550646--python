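"""Chlorophyll-channel segmentation against simulator ground truth and
analytically constructed fields."""

from dataclasses import replace

import numpy as np
import pytest

from greenseg import (
    CountSpec,
    FieldImage,
    SegmentationParams,
    evaluate_detection,
    extract_borders,
    segment_chlorophyll,
)
from greenseg.simulate import simulate_field


def _disk_field(centers, radius, shape=(200, 200), amplitude=3000.0, offset=100.0):
    """Sharp analytic disks on a constant offset, as a 16-bit field."""
    img = np.full(shape, offset)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for cy, cx in centers:
        img[np.hypot(yy - cy, xx - cx) <= radius] = offset + amplitude
    raster = img.astype(np.uint16)
    return FieldImage("SYN", 0, raster, np.full(shape, offset, np.uint16), 16)


class TestDegenerateInputs:
    def test_pure_noise_field_yields_zero_labels(self, small_config):
        cfg = replace(small_config, cells_per_field=CountSpec(mean=0, dispersion=8.0))
        field, _ = simulate_field(cfg, 0, "A01")
        assert segment_chlorophyll(field).max() == 0

    def test_constant_image_yields_zero_labels(self):
        flat = np.full((128, 128), 500, np.uint16)
        field = FieldImage("C", 0, flat, flat, 16)
        assert segment_chlorophyll(field).max() == 0

    def test_invalid_params_rejected(self, small_config):
        field, _ = simulate_field(small_config, 0, "A01")
        for bad in (
            SegmentationParams(smooth_sigma_px=-1),
            SegmentationParams(min_area_px=500, max_area_px=100),
            SegmentationParams(h_maxima_depth=0.0),
            SegmentationParams(threshold_method="magic"),
        ):
            with pytest.raises(ValueError):
                segment_chlorophyll(field, bad)


class TestDetectionAgainstGroundTruth:
    def test_sparse_field_detects_every_cell(self, sparse_config):
        """Non-touching bright cells: one label per ground-truth cell and
        centroids within 2 px of the matching region centroid."""
        field, truth = simulate_field(sparse_config, 0, "A01")
        mask = segment_chlorophyll(field)
        pad = truth["radius_px"].to_numpy() + 8  # surely border-excluded band
        h, w = field.shape
        interior = truth[
            (truth.centroid_row_px > pad)
            & (truth.centroid_row_px < h - 1 - pad)
            & (truth.centroid_col_px > pad)
            & (truth.centroid_col_px < w - 1 - pad)
        ]
        # every interior cell detected, no label without a truth cell
        assert len(interior) <= mask.max() <= len(truth)
        hits = mask[
            np.rint(truth.centroid_row_px).astype(int),
            np.rint(truth.centroid_col_px).astype(int),
        ]
        assert len(set(hits[hits > 0])) == mask.max()
        from scipy import ndimage as ndi

        centroids = np.asarray(
            ndi.center_of_mass(np.ones(mask.shape), mask, np.arange(1, mask.max() + 1))
        )
        for _, cell in interior.iterrows():
            d = np.hypot(
                centroids[:, 0] - cell.centroid_row_px,
                centroids[:, 1] - cell.centroid_col_px,
            )
            assert d.min() <= 2.0

    def test_precision_recall_on_sparse_fields(self, sparse_config):
        field, truth = simulate_field(sparse_config, 1, "A02")
        mask = segment_chlorophyll(field)
        pad = truth["radius_px"].to_numpy() + 8
        h, w = field.shape
        interior = truth[
            (truth.centroid_row_px > pad)
            & (truth.centroid_row_px < h - 1 - pad)
            & (truth.centroid_col_px > pad)
            & (truth.centroid_col_px < w - 1 - pad)
        ]
        # recall over cells that cannot have been border-excluded
        scores = evaluate_detection(
            mask, interior.centroid_row_px.to_numpy(), interior.centroid_col_px.to_numpy()
        )
        assert scores["recall"] >= 0.98
        # precision against the full ground truth (border cells may be kept)
        scores_all = evaluate_detection(
            mask, truth.centroid_row_px.to_numpy(), truth.centroid_col_px.to_numpy()
        )
        assert scores_all["precision"] >= 0.98


class TestClumpSplitting:
    def test_overlapping_pair_split_by_watershed(self):
        """Two disks 1.5 radii apart: split_clumps separates the two
        distance-transform maxima; without splitting they stay one region."""
        r = 20
        field = _disk_field([(100, 80), (100, 80 + int(1.5 * r))], r)
        split = segment_chlorophyll(field, SegmentationParams(split_clumps=True))
        merged = segment_chlorophyll(field, SegmentationParams(split_clumps=False))
        assert split.max() == 2
        assert merged.max() == 1

    def test_area_filter_removes_out_of_range_regions(self):
        field = _disk_field([(60, 60), (140, 140)], 20)
        params = SegmentationParams(min_area_px=80, max_area_px=400)  # disk ~1257 px
        assert segment_chlorophyll(field, params).max() == 0


class TestInvariances:
    def test_label_count_invariant_to_constant_offset(self, small_config):
        """Background subtraction + Otsu make detection insensitive to a
        camera offset shift."""
        field, _ = simulate_field(small_config, 0, "A01")
        shifted = FieldImage(
            field.well_id,
            field.field_index,
            (field.chl.astype(np.int64) + 500).clip(0, 65535).astype(np.uint16),
            field.gfp,
            16,
        )
        assert segment_chlorophyll(field).max() == segment_chlorophyll(shifted).max()

    def test_labels_consecutive_from_one(self, small_config):
        field, _ = simulate_field(small_config, 0, "A01")
        mask = segment_chlorophyll(field)
        labels = np.unique(mask)
        assert labels[0] == 0
        np.testing.assert_array_equal(labels[1:], np.arange(1, mask.max() + 1))

    def test_exclude_border_removes_edge_regions(self):
        field = _disk_field([(5, 100), (100, 100)], 20)
        mask_excl = segment_chlorophyll(field, SegmentationParams(exclude_border=True))
        mask_keep = segment_chlorophyll(field, SegmentationParams(exclude_border=False))
        assert mask_excl.max() == 1
        assert mask_keep.max() == 2
        edges = np.concatenate(
            [mask_excl[0], mask_excl[-1], mask_excl[:, 0], mask_excl[:, -1]]
        )
        assert (edges == 0).all()


class TestBorders:
    def test_square_label_has_perimeter_border(self):
        mask = np.zeros((30, 30), np.int32)
        mask[10:20, 10:20] = 1
        border = extract_borders(mask)
        assert border.sum() == 36  # 10x10 square outline
        assert (mask[border] == 1).all()

    def test_empty_mask_gives_empty_border(self):
        assert extract_borders(np.zeros((16, 16), np.int32)).sum() == 0

    def test_adjacent_labels_keep_identity(self):
        mask = np.zeros((20, 20), np.int32)
        mask[5:15, 2:10] = 1
        mask[5:15, 10:18] = 2
        border = extract_borders(mask)
        # the shared boundary column belongs to both cells' borders
        assert border[5:15, 9].all() and border[5:15, 10].all()
        # borders do not change the label raster itself
        assert set(np.unique(mask)) == {0, 1, 2}
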