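"""Segmentation, cleanup and boundary tracing of fruit silhouettes."""

import math

import numpy as np
import pytest
from scipy import ndimage

from mangograde import silhouette as sil


class TestSplitViews:
    def test_halving_a_frame(self):
        frame = np.zeros((850, 1600, 3), dtype=np.uint8)
        layout = sil.ViewLayout.halves(1600, 850)
        top, side = sil.split_views(frame, layout)
        assert top.shape == (850, 800, 3)
        assert side.shape == (850, 800, 3)

    def test_rectangle_out_of_bounds_rejected(self):
        frame = np.zeros((100, 100, 3), dtype=np.uint8)
        layout = sil.ViewLayout(top=(0, 0, 150, 100), side=(50, 0, 50, 100))
        with pytest.raises(ValueError):
            sil.split_views(frame, layout)

    def test_empty_rectangle_rejected(self):
        frame = np.zeros((100, 100, 3), dtype=np.uint8)
        layout = sil.ViewLayout(top=(0, 0, 100, 100), side=(100, 0, 0, 100))
        with pytest.raises(ValueError):
            sil.split_views(frame, layout)

    def test_each_crop_contains_one_blob(self, clean_scene, fruit_truth):
        h, w = clean_scene.image.shape[:2]
        top, side = sil.split_views(clean_scene.image, sil.ViewLayout.halves(w, h))
        for mask in (sil.threshold_top(sil.to_gray_b(top)), sil.threshold_side(side)):
            _, n = ndimage.label(mask, structure=np.ones((3, 3)))
            assert n == 1


class TestGrayAndThreshold:
    def test_blue_band_pick(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[0, 0] = (10, 20, 200)
        assert sil.to_gray_b(img)[0, 0] == 200

    def test_all_white_image(self):
        img = np.full((4, 4, 3), 255, dtype=np.uint8)
        assert np.all(sil.to_gray_b(img) == 255)

    def test_gray_rejects_single_channel(self):
        with pytest.raises(ValueError):
            sil.to_gray_b(np.zeros((4, 4), dtype=np.uint8))

    def test_threshold_intervals(self):
        gray = np.array([[10, 50, 150]], dtype=np.uint8)
        assert sil.threshold_top(gray).tolist() == [[False, True, False]]

    def test_uniform_bright_gives_empty_mask(self):
        assert not sil.threshold_top(np.full((5, 5), 255, dtype=np.uint8)).any()

    def test_inverted_stem_range_rejected(self):
        with pytest.raises(ValueError):
            sil.threshold_top(np.zeros((2, 2), dtype=np.uint8), stem_range=(30, 10))

    def test_stem_range_must_sit_below_background(self):
        with pytest.raises(ValueError):
            sil.threshold_top(np.zeros((2, 2), dtype=np.uint8), bg_thresh=90, stem_range=(0, 95))

    def test_fruit_darker_than_tray_in_blue(self, clean_scene, fruit_truth):
        top = clean_scene.image[:, :800]
        gray = sil.to_gray_b(top)
        assert gray[fruit_truth.top_mask].max() < gray[~fruit_truth.top_mask].min()

    def test_stem_pixels_excluded(self, noisy_scene):
        top_img = noisy_scene.image[:, :800]
        mask = sil.threshold_top(sil.to_gray_b(top_img))
        stem = noisy_scene.stem_mask[:, :800]
        assert stem.sum() > 0
        assert not (mask & stem).any()


class TestParticleRemovalAndHoles:
    def test_specks_removed_blob_kept(self, rng):
        mask = np.zeros((200, 200), dtype=bool)
        mask[50:150, 50:130] = True  # 8000 px blob
        for r, c in [(10, 10), (180, 20), (20, 180)]:
            mask[r : r + 3, c : c + 3] = True  # 9 px specks
        out = sil.remove_small_particles(mask, min_area=100)
        assert out[60, 60] and out.sum() == 8000

    def test_empty_mask_passthrough(self):
        assert not sil.remove_small_particles(np.zeros((10, 10), bool), 5).any()

    def test_largest_component_survives_min_area(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:8, 5:8] = True  # 9 px, below min_area
        out = sil.remove_small_particles(mask, min_area=100)
        assert out.sum() == 9

    def test_idempotent(self, rng):
        mask = rng.random((80, 80)) > 0.7
        once = sil.remove_small_particles(mask, 20)
        assert np.array_equal(once, sil.remove_small_particles(once, 20))

    def test_fill_annulus(self):
        yy, xx = np.ogrid[:101, :101]
        r2 = (yy - 50) ** 2 + (xx - 50) ** 2
        annulus = (r2 <= 40**2) & (r2 >= 20**2)
        disc = r2 <= 40**2
        assert np.array_equal(sil.fill_holes(annulus), disc)

    def test_fill_idempotent_on_hole_free(self, disc_mask):
        assert np.array_equal(sil.fill_holes(disc_mask), disc_mask)
        assert np.array_equal(sil.fill_holes(sil.fill_holes(disc_mask)), sil.fill_holes(disc_mask))

    def test_punched_specks_restored(self, fruit_truth):
        from mangograde.synthetic_scene import render_scene

        scene = render_scene(fruit_truth, noise={"specks": 12}, seed=9)
        top_img = scene.image[:, :800]
        mask = sil.threshold_top(sil.to_gray_b(top_img))
        cleaned = sil.fill_holes(sil.remove_small_particles(mask, 500))
        assert np.array_equal(cleaned, fruit_truth.top_mask)


class TestThresholdSide:
    def test_shadow_excluded_and_fruit_recalled(self, fruit_truth):
        from mangograde.synthetic_scene import render_scene

        scene = render_scene(fruit_truth, noise={"shadow": True}, seed=2)
        side_img = scene.image[:, 800:]
        mask = sil.threshold_side(side_img)
        shadow = scene.shadow_mask[:, 800:]
        assert shadow.sum() > 0
        assert not (mask & shadow).any()
        recall = (mask & fruit_truth.side_mask).sum() / fruit_truth.side_mask.sum()
        assert recall >= 0.98

    def test_no_shadow_makes_later_passes_vacuous(self, clean_scene):
        # without a shadow the G and second-B passes remove nothing; the only
        # difference from a single B threshold is the boundary smoothing of
        # the inter-pass median filter
        side_img = clean_scene.image[:, 800:]
        three_pass = sil.threshold_side(side_img)
        single = sil.to_gray_b(side_img) < 100
        jac = (three_pass & single).sum() / (three_pass | single).sum()
        assert jac >= 0.999

    def test_all_background_empty(self):
        img = np.full((20, 20, 3), 250, dtype=np.uint8)
        assert not sil.threshold_side(img).any()

    def test_even_median_rejected(self):
        img = np.zeros((10, 10, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            sil.threshold_side(img, median_size=6)


class TestBoundary:
    def test_solid_3x3_square_has_8_points(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1:4, 1:4] = True
        trace = sil.extract_boundary(mask)
        assert len(trace) == 8

    def test_circle_contour_length_bounds(self, disc_mask):
        # polygonal path length (diagonal steps count sqrt(2)) brackets the
        # true circumference from above, within the digital-perimeter bound
        trace = sil.extract_boundary(disc_mask)
        closed = np.vstack([trace.points, trace.points[:1]])
        steps = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        assert 2 * math.pi * 50 <= steps.sum() <= 2 * math.pi * 50 * math.sqrt(2) * 1.1

    def test_clockwise_orientation(self, disc_mask):
        assert sil.extract_boundary(disc_mask).signed_area() < 0

    def test_starts_topmost_then_leftmost(self, disc_mask):
        trace = sil.extract_boundary(disc_mask)
        ymin = trace.y.min()
        xmin = trace.x[trace.y == ymin].min()
        assert tuple(trace.points[0]) == (xmin, ymin)

    def test_consecutive_points_8_connected(self, fruit_truth):
        trace = sil.extract_boundary(fruit_truth.top_mask)
        diffs = np.abs(np.diff(np.vstack([trace.points, trace.points[:1]]), axis=0))
        assert diffs.max() == 1

    @pytest.mark.parametrize("shape", ["disc", "fruit"])
    def test_rasterize_round_trip(self, shape, disc_mask, fruit_truth):
        mask = disc_mask if shape == "disc" else fruit_truth.top_mask
        trace = sil.extract_boundary(mask)
        assert np.array_equal(sil.rasterize_boundary(trace, mask.shape), mask)

    def test_empty_and_multicomponent_rejected(self):
        with pytest.raises(ValueError):
            sil.extract_boundary(np.zeros((5, 5), bool))
        two = np.zeros((10, 10), bool)
        two[1:4, 1:4] = True
        two[6:9, 6:9] = True
        with pytest.raises(ValueError):
            sil.extract_boundary(two)


class TestMeasureMask:
    def test_solid_rectangle(self):
        mask = np.zeros((30, 40), dtype=bool)
        mask[5:15, 10:30] = True  # 10 rows x 20 cols
        m = sil.measure_mask(mask)
        assert m.area_px == 200
        assert m.bbox == (5, 10, 15, 30)

    def test_disc_area_within_1pct(self, disc_mask):
        m = sil.measure_mask(disc_mask)
        assert m.area_px == pytest.approx(math.pi * 50**2, rel=0.01)

    def test_ellipse_diameter_ratio(self):
        yy, xx = np.ogrid[:260, :260]
        ellipse = ((xx - 130) / 100.0) ** 2 + ((yy - 130) / 50.0) ** 2 <= 1.0
        m = sil.measure_mask(ellipse)
        assert m.max_diameter_px / m.min_diameter_px == pytest.approx(2.0, abs=0.02)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            sil.measure_mask(np.zeros((5, 5), bool))


def test_operations_leave_inputs_unmodified(noisy_scene):
    img = noisy_scene.image
    before = img.copy()
    gray = sil.to_gray_b(img[:, :800])
    mask = sil.threshold_top(gray)
    gray_before = gray.copy()
    mask_before = mask.copy()
    sil.remove_small_particles(mask, 500)
    sil.fill_holes(mask)
    sil.threshold_side(img[:, 800:])
    assert np.array_equal(img, before)
    assert np.array_equal(gray, gray_before)
    assert np.array_equal(mask, mask_before)


def test_segmentation_recovers_ground_truth(clean_scene, fruit_truth):
    """Noise-free scene: Jaccard(mask, truth) >= 0.99 in both views."""
    h, w = clean_scene.image.shape[:2]
    top_img, side_img = sil.split_views(clean_scene.image, sil.ViewLayout.halves(w, h))
    top = sil.fill_holes(sil.remove_small_particles(sil.threshold_top(sil.to_gray_b(top_img)), 500))
    side = sil.fill_holes(sil.remove_small_particles(sil.threshold_side(side_img), 500))
    for mask, truth in ((top, fruit_truth.top_mask), (side, fruit_truth.side_mask)):
        jac = (mask & truth).sum() / (mask | truth).sum()
        assert jac >= 0.99
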