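"""Segmentation stages against hand computations and brute-force oracles."""

import numpy as np
import pytest

from abquant.io import Micrograph, RegionOfInterest
from abquant.segment import (
    LabeledObjects,
    SegmentationConfig,
    adaptive_threshold,
    apply_roi,
    filter_small_objects,
    label_objects,
    morphological_open,
)
from abquant.simulate import SimulationConfig, generate_micrograph, rasterize_truth

from oracles import brute_open, flood_fill_label, point_in_polygon


class TestAdaptiveThreshold:
    def test_constant_image_is_all_background(self):
        img = Micrograph(np.full((40, 40), 17.0), 1.0)
        mask = adaptive_threshold(img, window_px=5, offset=0.0)
        assert not mask.values.any()

    def test_single_bright_pixel_hand_computed(self):
        # 100 at (3,3), zeros elsewhere, window 3, offset 0.  The bright
        # pixel sees mean 100/9 and fires; each 8-neighbor sees the same
        # mean but carries value 0, so only one pixel is foreground.
        img = np.zeros((7, 7))
        img[3, 3] = 100.0
        mask = adaptive_threshold(Micrograph(img, 1.0), window_px=3, offset=0.0)
        assert mask.values[3, 3]
        assert mask.count() == 1

    def test_offset_suppresses_the_bright_pixel(self):
        img = np.zeros((7, 7))
        img[3, 3] = 100.0
        # mean is 100/9 = 11.1; value 100 > 11.1 + 88 fails
        mask = adaptive_threshold(Micrograph(img, 1.0), window_px=3, offset=89.0)
        assert mask.count() == 0

    @pytest.mark.parametrize("window", [2, 1, 4])
    def test_even_or_small_window_rejected(self, window):
        with pytest.raises(ValueError):
            adaptive_threshold(Micrograph(np.ones((10, 10)), 1.0), window_px=window)

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            adaptive_threshold(Micrograph(np.ones((10, 10)), 1.0), window_px=11)

    def test_recovers_planted_object_footprints(self):
        # peak - background >> noise: every truth pixel must be foreground
        cfg = SimulationConfig(seed=7)
        img, truth, _ = generate_micrograph(cfg)
        lab = rasterize_truth(truth, cfg.image_shape, cfg.pixel_size_um)
        mask = adaptive_threshold(img, window_px=129, offset=6.0)
        for obj_id in range(1, lab.n_objects + 1):
            footprint = lab.labels == obj_id
            assert mask.values[footprint].mean() >= 0.95


class TestMorphologicalOpen:
    def test_radius_zero_is_identity(self, rng):
        mask = rng.random((30, 30)) < 0.3
        out = morphological_open(mask, 0)
        assert np.array_equal(out.values, mask)

    def test_isolated_pixel_removed(self):
        mask = np.zeros((15, 15), bool)
        mask[7, 7] = True
        assert morphological_open(mask, 1).count() == 0

    def test_full_grid_square_unchanged(self):
        # a set the structuring element fits in everywhere is a fixed point
        mask = np.ones((21, 21), bool)
        out = morphological_open(mask, 3)
        assert np.array_equal(out.values, mask)
        assert np.array_equal(brute_open(mask, 3), mask)

    @pytest.mark.parametrize("radius", [1, 2, 3])
    def test_matches_brute_force_on_random_masks(self, rng, radius):
        for density in (0.2, 0.5, 0.8):
            mask = rng.random((24, 24)) < density
            got = morphological_open(mask, radius).values
            assert np.array_equal(got, brute_open(mask, radius))

    @pytest.mark.parametrize("radius", [1, 2])
    def test_idempotent_and_anti_extensive(self, rng, radius):
        for _ in range(20):
            mask = rng.random((32, 32)) < rng.uniform(0.1, 0.9)
            once = morphological_open(mask, radius).values
            twice = morphological_open(once, radius).values
            assert np.array_equal(once, twice)
            assert not (once & ~mask).any()  # output contained in input


class TestApplyRoi:
    def test_full_frame_roi_keeps_mask(self, rng):
        mask = rng.random((20, 20)) < 0.4
        roi = RegionOfInterest(
            np.array([(-0.5, -0.5), (-0.5, 19.5), (19.5, 19.5), (19.5, -0.5)])
        )
        out = apply_roi(mask, roi)
        assert np.array_equal(out.values, mask)

    def test_pixel_center_count_matches_brute_force(self):
        mask = np.ones((20, 20), bool)
        verts = [(2.5, 3.5), (2.5, 11.5), (9.5, 11.5), (9.5, 3.5)]
        roi = RegionOfInterest(np.array(verts))
        out = apply_roi(mask, roi)
        expected = sum(
            point_in_polygon(r, c, verts) for r in range(20) for c in range(20)
        )
        assert expected == 7 * 8  # rows 3..9, cols 4..11
        assert out.count() == expected

    def test_boundary_pixels_are_inside(self):
        mask = np.ones((10, 10), bool)
        roi = RegionOfInterest(np.array([(2.0, 2.0), (2.0, 5.0), (5.0, 5.0), (5.0, 2.0)]))
        out = apply_roi(mask, roi)
        assert out.count() == 16  # 4x4 centers, corners included

    def test_triangle_roi_matches_brute_force(self, rng):
        mask = rng.random((25, 25)) < 0.6
        verts = [(1.2, 2.1), (20.7, 4.3), (9.6, 22.4)]
        out = apply_roi(mask, RegionOfInterest(np.array(verts)))
        for r in range(25):
            for c in range(25):
                expect = mask[r, c] and point_in_polygon(r, c, verts)
                assert out.values[r, c] == expect

    def test_disjoint_roi_empties_mask(self):
        mask = np.ones((10, 10), bool)
        roi = RegionOfInterest(np.array([(2.0, 2.0), (2.0, 6.0), (6.0, 6.0), (6.0, 2.0)]))
        mask[2:7, 2:7] = False
        assert apply_roi(mask, roi).count() == 0

    def test_roi_outside_frame_rejected(self):
        mask = np.ones((10, 10), bool)
        roi = RegionOfInterest(np.array([(50.0, 50.0), (50.0, 60.0), (60.0, 60.0), (60.0, 50.0)]))
        with pytest.raises(ValueError, match="outside"):
            apply_roi(mask, roi)


class TestLabelObjects:
    def test_empty_mask(self):
        out = label_objects(np.zeros((8, 8), bool), 8)
        assert out.n_objects == 0

    def test_diagonal_pixels_connectivity(self):
        mask = np.zeros((5, 5), bool)
        mask[1, 1] = mask[2, 2] = True
        assert label_objects(mask, 8).n_objects == 1
        assert label_objects(mask, 4).n_objects == 2

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        for _ in range(100):
            shape = (int(rng.integers(4, 33)), int(rng.integers(4, 33)))
            mask = rng.random(shape) < rng.uniform(0.1, 0.7)
            got = label_objects(mask, connectivity)
            expected = flood_fill_label(mask, connectivity)
            # raster-order numbering makes the label images identical
            assert np.array_equal(got.labels, expected)
            assert got.n_objects == expected.max()

    def test_invalid_connectivity(self):
        with pytest.raises(ValueError):
            label_objects(np.ones((4, 4), bool), 6)


class TestFilterSmallObjects:
    def test_drops_and_renumbers(self):
        mask = np.zeros((12, 12), bool)
        mask[1, 1] = True  # 1 px
        mask[4:7, 4:7] = True  # 9 px
        mask[9, 9:11] = True  # 2 px
        lab = label_objects(mask, 8)
        out = filter_small_objects(lab, min_area_um2=2.0, pixel_size_um=1.0)
        assert out.n_objects == 2
        assert set(np.unique(out.labels)) == {0, 1, 2}

    def test_zero_threshold_is_identity(self):
        mask = np.zeros((6, 6), bool)
        mask[2, 2] = True
        lab = label_objects(mask, 8)
        assert filter_small_objects(lab, 0.0, 1.0) is lab


class TestPipelineMonotonicity:
    def test_foreground_never_increases(self, rng):
        cfg = SimulationConfig(image_shape=(384, 384), n_oligomers=10, n_plaques=2, seed=11)
        img, _, roi = generate_micrograph(cfg)
        m0 = adaptive_threshold(img, window_px=129, offset=6.0)
        m1 = morphological_open(m0, 1)
        m2 = apply_roi(m1, roi)
        assert m0.count() >= m1.count() >= m2.count()


class TestSegmentationConfig:
    def test_validation(self):
        SegmentationConfig()  # defaults valid
        with pytest.raises(ValueError):
            SegmentationConfig(window_px=10)
        with pytest.raises(ValueError):
            SegmentationConfig(connectivity=5)
        with pytest.raises(ValueError):
            SegmentationConfig(class_cutoff_diameter_um=0)

    def test_labeled_objects_invariant(self):
        with pytest.raises(ValueError):
            LabeledObjects(np.array([[0, 2], [0, 0]]), 1)  # label 1 missing
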