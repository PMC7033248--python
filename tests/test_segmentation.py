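"""Segmentation pipeline: background subtraction through region extraction."""

import numpy as np
import pytest
from skimage.filters import threshold_otsu

import adenoquant as aq
from adenoquant.segmentation import BLUE_FLOOR, isodata_threshold

SCALE = 0.05  # mm per pixel unless a test says otherwise


def _card(h=60, w=80, rgb=(70, 110, 170), noise=0, seed=0):
    rng = np.random.default_rng(seed)
    img = np.tile(np.array(rgb, np.float64), (h, w, 1))
    img += rng.normal(0, noise, img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


class TestSubtractBackground:
    def test_pure_card_vanishes(self):
        img = aq.CalibratedImage(_card(noise=3, seed=4), SCALE)
        gray = aq.subtract_background(img)
        assert gray.pixels.max() == 0

    def test_white_square_retained(self):
        px = _card(200, 200)
        px[70:130, 70:130] = 255
        gray = aq.subtract_background(aq.CalibratedImage(px, SCALE))
        assert gray.pixels[100, 100] > 200
        assert gray.pixels[10, 10] == 0

    def test_per_pixel_formula_oracle(self):
        """Output equals an independent per-pixel loop over the documented rule."""
        rng = np.random.default_rng(7)
        px = _card(40, 50, noise=4, seed=1)
        px[10:25, 15:35] = rng.integers(180, 240, (15, 20, 3))
        gray = aq.subtract_background(aq.CalibratedImage(px, SCALE))

        b = px[..., 2].astype(int) - np.maximum(px[..., 0], px[..., 1]).astype(int)
        cut = threshold_otsu(b.ravel().astype(float))
        if b[b <= cut].mean() > BLUE_FLOOR:
            cut = BLUE_FLOOR
        expected = np.zeros(px.shape[:2], dtype=np.uint8)
        for r in range(px.shape[0]):
            for c in range(px.shape[1]):
                if b[r, c] <= cut:
                    luma = (0.299 * px[r, c, 0] + 0.587 * px[r, c, 1]
                            + 0.114 * px[r, c, 2])
                    expected[r, c] = round(luma)
        np.testing.assert_array_equal(gray.pixels, expected)

    def test_preserves_dimensions_and_scale(self):
        img = aq.CalibratedImage(_card(), 0.07, image_id="i", mouse_id="m")
        gray = aq.subtract_background(img)
        assert gray.pixels.shape == (60, 80)
        assert gray.scale_mm_per_px == 0.07


class TestScaleAnnotation:
    def test_two_point_ruler(self):
        # 10 mm ruler segment spanning 200 px -> 0.05 mm/px
        assert aq.scale_from_two_points((10, 10), (10, 210), 10.0) == pytest.approx(0.05)

    def test_degenerate_annotation_rejected(self):
        with pytest.raises(ValueError):
            aq.scale_from_two_points((5, 5), (5, 5), 10.0)


class TestAutoThreshold:
    def test_perfectly_bimodal(self):
        px = np.zeros((20, 20), np.uint8)
        px[5:10, 5:10] = 255
        mask = aq.auto_threshold(aq.GrayImage(px, SCALE))
        np.testing.assert_array_equal(mask, px == 255)

    def test_intermeans_fixed_point_oracle(self):
        """Stated histogram vs a brute-force search for the recurrence's fixed point."""
        hist = np.zeros(256)
        hist[10], hist[200], hist[100] = 1000, 1000, 50
        t = isodata_threshold(hist)
        levels = np.arange(256)
        fixed_points = []
        for cand in range(255):
            lo, hi = hist[: cand + 1], hist[cand + 1 :]
            if lo.sum() == 0 or hi.sum() == 0:
                continue
            mb = (lo * levels[: cand + 1]).sum() / lo.sum()
            ma = (hi * levels[cand + 1 :]).sum() / hi.sum()
            if int((mb + ma) / 2) == cand:
                fixed_points.append(cand)
        assert t in fixed_points

    def test_constant_image_empty_mask(self):
        mask = aq.auto_threshold(aq.GrayImage(np.zeros((10, 10), np.uint8), SCALE))
        assert not mask.any()


class TestDespeckle:
    def test_singleton_removed_solid_kept(self):
        m = np.zeros((40, 40), bool)
        m[5, 5] = True
        m[15:35, 15:35] = True
        out = aq.despeckle(m)
        assert not out[5, 5]
        assert out[16:34, 16:34].all()

    def test_sliding_window_median_oracle(self):
        rng = np.random.default_rng(3)
        m = rng.random((25, 30)) < 0.45
        out = aq.despeckle(m)
        expected = np.zeros_like(m)
        padded = np.pad(m, 1, constant_values=False)
        for r in range(m.shape[0]):
            for c in range(m.shape[1]):
                expected[r, c] = np.median(padded[r : r + 3, c : c + 3]) > 0.5
        np.testing.assert_array_equal(out, expected)

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            aq.despeckle(np.zeros((5, 5), np.uint8))


class TestExtractRegions:
    def test_area_filter_at_cutoff(self):
        # 0.15 mm² = 60 px and 0.25 mm² = 100 px at 0.05 mm/px
        mask = np.zeros((60, 60), bool)
        mask[5:11, 5:15] = True     # 60 px
        mask[30:40, 30:40] = True   # 100 px
        gray = aq.GrayImage(np.full((60, 60), 150, np.uint8), SCALE)
        label_map, feats = aq.extract_regions(mask, gray)
        assert label_map.n_regions == 1
        assert len(feats) == 1
        assert feats[0].Area == pytest.approx(0.25)

    def test_empty_mask(self):
        gray = aq.GrayImage(np.zeros((30, 30), np.uint8), SCALE)
        _, feats = aq.extract_regions(np.zeros((30, 30), bool), gray)
        assert feats == []

    def test_areas_match_pixel_count_oracle(self):
        mask = np.zeros((80, 80), bool)
        mask[5:19, 5:19] = True     # 196 px
        mask[40:55, 40:60] = True   # 300 px
        gray = aq.GrayImage(np.full((80, 80), 99, np.uint8), SCALE)
        _, feats = aq.extract_regions(mask, gray)
        areas = sorted(f.Area for f in feats)
        # independent counting loop
        from scipy import ndimage
        lab, n = ndimage.label(mask, structure=np.ones((3, 3)))
        expected = sorted((lab == i).sum() * SCALE**2 for i in range(1, n + 1))
        assert areas == pytest.approx(expected)


class TestRunFeatureCounter:
    def test_planted_lesion_recall_and_area(self):
        spec = aq.SynthImageSpec(seed=11, n_lesions=10,
                                 lesion_area_range_mm2=(0.3, 2.0))
        img, truth = aq.generate_image(spec)
        feats, label_map = aq.run_featurecounter(img)
        assert len(feats) == 10
        # each ground-truth lesion is hit by exactly one feature, with
        # measured area within 15% of the analytic ellipse area
        for i, true_area in enumerate(truth.lesion_areas_mm2, start=1):
            lesion = truth.lesion_labels == i
            hits = set(np.unique(label_map.labels[lesion])) - {0}
            assert len(hits) == 1
            feat = feats[hits.pop() - 1]
            assert feat.Area == pytest.approx(true_area, rel=0.15)

    def test_control_image_nearly_clean(self):
        img, _ = aq.generate_image(aq.SynthImageSpec(seed=5, n_lesions=0))
        feats, _ = aq.run_featurecounter(img)
        assert len(feats) <= 2

    def test_deterministic(self):
        img, _ = aq.generate_image(aq.SynthImageSpec(seed=3, n_lesions=4))
        f1, _ = aq.run_featurecounter(img)
        f2, _ = aq.run_featurecounter(img)
        assert aq.features_to_frame(f1).equals(aq.features_to_frame(f2))

    def test_invariants(self):
        img, _ = aq.generate_image(aq.SynthImageSpec(seed=9, n_lesions=6,
                                                     n_fat_patches=2,
                                                     n_edge_streaks=2))
        feats, _ = aq.run_featurecounter(img)
        img_area = img.pixels.shape[0] * img.pixels.shape[1] * SCALE**2
        assert all(f.Area >= 0.2 for f in feats)
        assert sum(f.Area for f in feats) <= img_area


class TestManualMask:
    def _gray(self):
        return aq.GrayImage(np.full((60, 60), 120, np.uint8), SCALE)

    def test_three_blobs(self):
        mask = np.zeros((60, 60), np.uint8)
        mask[2:6, 2:6] = 255          # 16 px: below 0.2 mm², still kept
        mask[20:30, 20:30] = 255
        mask[45:55, 10:30] = 255
        feats, _ = aq.ingest_manual_mask(mask, self._gray())
        assert len(feats) == 3

    def test_path_equivalence_with_automatic(self):
        mask = np.zeros((60, 60), bool)
        mask[10:30, 10:30] = True
        gray = self._gray()
        manual, _ = aq.ingest_manual_mask(mask, gray)
        _, auto = aq.extract_regions(mask, gray)
        assert manual[0].measures() == auto[0].measures()

    def test_rejects_non_binary(self):
        mask = np.full((60, 60), 7, np.uint8)
        with pytest.raises(ValueError):
            aq.ingest_manual_mask(mask, self._gray())

    def test_areas_match_pixel_count(self):
        mask = np.zeros((60, 60), bool)
        mask[5:12, 5:25] = True
        feats, _ = aq.ingest_manual_mask(mask, self._gray())
        assert feats[0].Area == pytest.approx(7 * 20 * SCALE**2)
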