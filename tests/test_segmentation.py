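"""FAZ segmentation: cropping, edges, morphology, region selection."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from conftest import dice
from oracles import close_bruteforce, random_blob
from octafaz.segmentation import (SegmentationConfig, close_with_lines,
                                  crop_description, crop_roi,
                                  detect_edges_prewitt, embed_mask,
                                  line_footprint, remove_false_positives,
                                  segment_faz, _closing)
from octafaz.synthetic import PhantomSpec, make_faz_phantom
from octafaz.types import EnFaceImage, SegmentationError


def _image(pixels, scale=1.0):
    return EnFaceImage(pixels=np.asarray(pixels, dtype=np.uint8),
                       scale=scale)


class TestCrops:
    def test_header_crop_arithmetic(self):
        img = _image(np.zeros((440, 420)))
        out = crop_description(img, 20)
        assert out.pixels.shape == (420, 420)
        assert out.scale == img.scale

    def test_zero_crop_is_identity(self):
        img = _image(np.arange(100).reshape(10, 10) % 256)
        assert np.array_equal(crop_description(img, 0).pixels, img.pixels)

    def test_crop_whole_image_rejected(self):
        with pytest.raises(ValueError):
            crop_description(_image(np.zeros((440, 420))), 440)

    def test_roi_shape_and_offset(self):
        img = _image(np.zeros((420, 420)))
        roi, off = crop_roi(img, (210, 210), 100)
        assert roi.pixels.shape == (201, 201)
        assert off == (110, 110)

    def test_roi_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            crop_roi(_image(np.zeros((420, 420))), (10, 10), 100)

    def test_embed_then_crop_round_trip(self, rng):
        img = _image(rng.integers(0, 255, (300, 300)))
        roi, off = crop_roi(img, (150, 150), 40)
        mask = rng.random(roi.pixels.shape) > 0.5
        full = embed_mask(mask, off, img.pixels.shape)
        again = full[off[0]:off[0] + 81, off[1]:off[1] + 81]
        assert np.array_equal(again, mask)


class TestPrewitt:
    def test_constant_image_no_edges(self):
        assert not detect_edges_prewitt(np.full((50, 50), 77.0), 0.1).any()

    def test_vertical_step_edges_confined_to_three_columns(self):
        img = np.zeros((30, 30))
        img[:, 15:] = 200.0
        edges = detect_edges_prewitt(img, 0.5)
        cols = np.unique(np.nonzero(edges)[1])
        assert set(cols) <= {14, 15, 16}
        assert edges.any()

    def test_disk_phantom_edges_ring_near_boundary(self):
        spec = PhantomSpec(faz_shape="disk", radius_mm=40 * 6 / 420,
                           vessel_fraction=0.0, noise_sd=0.0, seed=0)
        img, truth = make_faz_phantom(spec)
        edges = detect_edges_prewitt(img.pixels.astype(float), 0.2)
        dist_to_boundary = ndi.distance_transform_edt(
            ~(truth.faz_mask ^ ndi.binary_erosion(truth.faz_mask)))
        assert dist_to_boundary[edges].max() <= 2.0

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            detect_edges_prewitt(np.zeros((5, 5)), 0.0)


class TestLineClosing:
    def test_bridges_collinear_gap(self):
        grid = np.zeros((20, 20), dtype=bool)
        grid[10, 2:8] = True
        grid[10, 11:17] = True  # 3-px gap < line length 5
        out = close_with_lines(grid, 5, (0.0,))
        labels, n = ndi.label(out, structure=np.ones((3, 3), int))
        assert n == 1
        assert out[10, 8:11].all()

    def test_empty_grid_stays_empty(self):
        assert not close_with_lines(np.zeros((10, 10), bool), 5).any()

    def test_length_one_is_identity(self, rng):
        grid = rng.random((15, 15)) > 0.7
        assert np.array_equal(close_with_lines(grid, 1), grid)

    def test_extensive_per_orientation(self, rng):
        for _ in range(20):
            grid = random_blob(rng, 16)
            out = close_with_lines(grid, 5)
            assert (out | grid).sum() == out.sum()  # output superset

    def test_matches_bruteforce_closing(self, rng):
        """Per-orientation closing equals the set-definition oracle."""
        for angle in (0.0, 45.0, 90.0):
            fp = line_footprint(5, angle)
            for _ in range(25):
                grid = random_blob(rng, 16)
                assert np.array_equal(_closing(grid, fp),
                                      close_bruteforce(grid, fp))


class TestFalsePositiveRemoval:
    def test_largest_component_kept(self):
        grid = np.zeros((40, 60), dtype=bool)
        grid[5:15, 5:15] = True   # 100 px
        grid[25:31, 40:45] = True  # 30 px
        out = remove_false_positives(grid, 1, 10)
        assert out[5:15, 5:15].all()
        assert not out[25:31, 40:45].any()

    def test_equal_sizes_tie_broken_by_centroid(self):
        grid = np.zeros((40, 40), dtype=bool)
        grid[2:7, 2:7] = True
        grid[30:35, 30:35] = True
        out = remove_false_positives(grid, 1, 5)
        assert out[2:7, 2:7].all() and not out[30:35, 30:35].any()

    def test_all_below_minimum_raises(self):
        grid = np.zeros((20, 20), dtype=bool)
        grid[3, 3] = True
        with pytest.raises(SegmentationError):
            remove_false_positives(grid, 1, 50)

    def test_disk_radius_monotonicity(self, rng):
        """Growing the closing disk never increases the surviving
        component count."""
        from skimage.morphology import disk as dfp
        for _ in range(25):
            grid = random_blob(rng, 32, sigma=1.5)
            counts = []
            for r in (1, 2, 3, 5):
                closed = _closing(grid, dfp(r).astype(bool))
                counts.append(ndi.label(closed,
                                        np.ones((3, 3), int))[1])
            assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestSegmentFaz:
    def test_disk_phantom_recovered(self):
        spec = PhantomSpec(faz_shape="disk", radius_mm=50 * 6 / 420, seed=1)
        img, truth = make_faz_phantom(spec)
        mask = segment_faz(img)
        assert dice(mask.infill, truth.faz_mask) >= 0.90
        assert mask.infill.shape == img.pixels.shape

    def test_deterministic(self):
        img, _ = make_faz_phantom(PhantomSpec(seed=5))
        m1 = segment_faz(img)
        m2 = segment_faz(img)
        assert np.array_equal(m1.infill, m2.infill)
        assert np.array_equal(m1.outline, m2.outline)

    def test_single_component_no_holes(self):
        img, _ = make_faz_phantom(PhantomSpec(seed=8))
        m = segment_faz(img)
        labels, n = ndi.label(m.infill, np.ones((3, 3), int))
        assert n == 1
        assert np.array_equal(ndi.binary_fill_holes(m.infill), m.infill)

    def test_outline_is_boundary_of_infill(self):
        img, _ = make_faz_phantom(PhantomSpec(seed=8))
        m = segment_faz(img)
        boundary = m.infill & ~ndi.binary_erosion(m.infill)
        outline_mask = np.zeros_like(m.infill)
        outline_mask[m.outline[:, 0], m.outline[:, 1]] = True
        assert outline_mask[boundary].all() or boundary[outline_mask].all()
        assert m.infill[m.outline[:, 0], m.outline[:, 1]].all()

    def test_no_faz_image_fails_or_flags_tiny_region(self):
        """Pure vessel/noise images must not yield a plausible FAZ."""
        failures = 0
        for seed in range(5):
            spec = PhantomSpec(faz_shape="disk", radius_mm=0.01,
                               noise_sd=10.0, seed=seed)
            img, _ = make_faz_phantom(spec)
            try:
                m = segment_faz(img)
                area = m.area_px * spec.scale ** 2
                assert area < 0.08  # below any plausible FAZ
            except SegmentationError:
                failures += 1
        assert failures >= 3

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SegmentationConfig(prewitt_threshold=0.0)
        with pytest.raises(ValueError):
            SegmentationConfig(line_length_px=0)
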