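"""Adaptive binarization, component labeling and nucleolus detection."""

import numpy as np
import pytest
from scipy import ndimage

from colonyflow import (GrayFrame, PipelineConfig, adaptive_binarize,
                        detect_nucleoli, filter_by_size, label_components)
from colonyflow.model import LabeledRegions


class TestAdaptiveBinarize:
    def test_constant_image_all_background(self):
        img = np.full((64, 64), 0.5)
        for pol in ("dark", "bright"):
            assert not adaptive_binarize(img, 41, 0.05, pol).any()

    def test_single_dark_pixel_detected_exactly(self):
        """Direct evaluation of the local-mean inequality at every pixel."""
        img = np.ones((64, 64))
        img[30, 30] = 0.0
        mask = adaptive_binarize(img, 41, 0.05, "dark")
        assert mask[30, 30] and mask.sum() == 1
        # symmetric polarity finds nothing bright
        assert not adaptive_binarize(img, 41, 0.05, "bright").any()

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            adaptive_binarize(np.zeros((64, 64)), 40, 0.05, "dark")

    def test_box_mean_matches_manual_window_average(self, rng):
        img = rng.random((20, 20))
        mask = adaptive_binarize(img, 5, 0.02, "dark", method="box")
        r, c = 10, 10
        local = img[r - 2:r + 3, c - 2:c + 3].mean()
        assert mask[r, c] == (img[r, c] < local - 0.02)

    def test_affine_intensity_invariance(self, rng):
        """Adaptive thresholding is equivariant under a*I + b with offset a*o."""
        for _ in range(10):
            img = ndimage.gaussian_filter(rng.random((64, 64)), 2)
            a, b = rng.uniform(0.3, 0.9), rng.uniform(0.0, 0.1)
            m1 = adaptive_binarize(img, 15, 0.02, "dark")
            m2 = adaptive_binarize(a * img + b, 15, a * 0.02, "dark")
            np.testing.assert_array_equal(m1, m2)


class TestLabelComponents:
    def test_diagonal_pixels_connectivity(self):
        mask = np.zeros((5, 5), bool)
        mask[1, 1] = mask[2, 2] = True
        assert label_components(mask, 8).n_regions == 1
        assert label_components(mask, 4).n_regions == 2

    def test_empty_mask(self):
        regions = label_components(np.zeros((5, 5), bool))
        assert regions.n_regions == 0

    def test_labels_raster_ordered_with_consistent_tables(self, rng):
        mask = rng.random((40, 40)) > 0.7
        regions = label_components(mask, 8)
        assert regions.label_image.max() == regions.n_regions
        # label 1 owns the first foreground pixel in raster order
        first = np.argwhere(mask)[0]
        assert regions.label_image[tuple(first)] == 1
        for k in range(regions.n_regions):
            area = (regions.label_image == k + 1).sum()
            assert area == regions.areas[k]
            rr, cc = np.where(regions.label_image == k + 1)
            r0, c0 = regions.centroids[k]
            assert rr.min() <= r0 <= rr.max() and cc.min() <= c0 <= cc.max()


class TestFilterBySize:
    def _regions_with_areas(self, areas):
        img = np.zeros((len(areas) * 3, max(areas) + 2), bool)
        for i, a in enumerate(areas):
            img[3 * i, 1:1 + a] = True
        return label_components(img, 8)

    def test_inclusive_range_boundaries(self):
        """Areas 11 and 73 are rejected; the stated limits 12 and 72 are kept."""
        regions = self._regions_with_areas([11, 12, 72, 73])
        kept = filter_by_size(regions, 12, 72)
        assert sorted(kept.areas.tolist()) == [12, 72]

    def test_no_survivors_and_all_survivors(self):
        regions = self._regions_with_areas([5, 6])
        assert filter_by_size(regions, 10, 20).n_regions == 0
        kept = filter_by_size(regions, 1, 100)
        assert kept.n_regions == 2
        assert sorted(np.unique(kept.label_image).tolist()) == [0, 1, 2]

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            filter_by_size(self._regions_with_areas([5]), 10, 5)


def _disc(shape, center, radius):
    rr = np.arange(shape[0])[:, None] - center[0]
    cc = np.arange(shape[1])[None, :] - center[1]
    return np.hypot(rr, cc) < radius


def _ring(shape, center, r_in, r_out):
    rr = np.arange(shape[0])[:, None] - center[0]
    cc = np.arange(shape[1])[None, :] - center[1]
    d = np.hypot(rr, cc)
    return (d >= r_in) & (d < r_out)


def _enclosure_oracle(mask, candidate):
    """Brute-force check: background flood fill from the border never
    touches the candidate region (4-connected background)."""
    others_bg = ~(mask & ~candidate)
    reach = np.zeros_like(mask)
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    seeds = others_bg & border
    lab, _ = ndimage.label(others_bg, ndimage.generate_binary_structure(2, 1))
    reach = np.isin(lab, np.unique(lab[seeds & (lab > 0)]))
    return not (reach & candidate).any()


class TestDetectNucleoli:
    def _frame(self, img):
        return GrayFrame(img, 0)

    def test_disc_inside_annulus_detected_at_center(self):
        img = np.full((96, 96), 0.9)
        img[_disc(img.shape, (48, 48), 3)] = 0.1         # nucleolus, ~25 px
        img[_ring(img.shape, (48, 48), 8, 10)] = 0.3     # nuclear ring
        pts = detect_nucleoli(self._frame(img))
        assert pts.points.tolist() == [[48, 48]]
        # independent flood-fill oracle agrees that the disc is enclosed
        mask = adaptive_binarize(img, 41, 0.03, "dark")
        assert _enclosure_oracle(mask, _disc(img.shape, (48, 48), 3) & mask)

    def test_disc_without_ring_rejected(self):
        img = np.full((96, 96), 0.9)
        img[_disc(img.shape, (48, 48), 3)] = 0.1
        assert len(detect_nucleoli(self._frame(img))) == 0

    def test_crescent_with_external_centroid_rejected(self):
        img = np.full((96, 96), 0.9)
        # C-shape: ring sector with a gap; its centroid falls in the cavity
        rr = np.arange(96)[:, None] - 48.0
        cc = np.arange(96)[None, :] - 48.0
        d = np.hypot(rr, cc)
        crescent = (d >= 4) & (d < 6) & (cc < 2)
        assert 12 <= crescent.sum() <= 72
        img[crescent] = 0.1
        img[_ring(img.shape, (48, 48), 10, 12)] = 0.3    # enclosing ring present
        assert len(detect_nucleoli(self._frame(img))) == 0

    def test_recall_and_decoy_rejection_on_scene(self, small_scene):
        frames, truth = small_scene
        pts = detect_nucleoli(frames[0])
        true_pts = truth.nucleoli[0].points
        from scipy.spatial import cKDTree
        d, _ = cKDTree(pts.points).query(true_pts)
        assert (d <= 2).mean() >= 0.9            # recall on ringed nucleoli
        outside = ~truth.colony_masks[0]
        assert sum(outside[r, c] for r, c in pts.points) == 0   # no decoys

    def test_detected_points_lie_on_filtered_foreground(self, small_scene):
        frames, _ = small_scene
        cfg = PipelineConfig()
        mask = adaptive_binarize(frames[0].pixels, cfg.binarize_window,
                                 cfg.binarize_offset, "dark")
        regions = filter_by_size(label_components(mask, 8),
                                 cfg.nucleolus_min_px, cfg.nucleolus_max_px)
        for r, c in detect_nucleoli(frames[0]).points:
            assert regions.label_image[r, c] > 0
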