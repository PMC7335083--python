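import numpy as np
import pytest

from laryq import segmentation as seg
from laryq.compensation import histogram_shift
from laryq.errors import InvalidInputError, RegionNotFoundError
from laryq.phantom import PhantomParams, make_phantom


class TestGlottisThreshold:
    def test_constant_image(self):
        assert seg.glottis_threshold(np.full((8, 8), 77.0)) == pytest.approx(77.0)

    def test_two_level_closed_form(self):
        # half 100, half 200: mu=150, sigma=50, TH=100
        g = np.concatenate([np.full(50, 100.0), np.full(50, 200.0)]).reshape(10, 10)
        assert seg.glottis_threshold(g) == pytest.approx(100.0)

    def test_clamped_to_valid_range(self):
        assert 0.0 <= seg.glottis_threshold(np.zeros((4, 4))) <= 255.0


class TestBinarize:
    def test_constant_below_threshold_full_mask(self):
        g = np.full((5, 5), 50.0)
        assert seg.binarize_dark(g, 60.0).all()

    def test_threshold_at_min_empty_mask(self):
        g = np.full((5, 5), 50.0)
        assert not seg.binarize_dark(g, 50.0).any()

    def test_two_level_dark_mask_empty_at_th(self):
        g = np.concatenate([np.full(50, 100.0), np.full(50, 200.0)]).reshape(10, 10)
        th = seg.glottis_threshold(g)
        assert not seg.binarize_dark(g, th).any()

    def test_bright_mask(self):
        g = np.concatenate([np.full(50, 100.0), np.full(50, 200.0)]).reshape(10, 10)
        bright = seg.binarize_bright(g, k=0.5)
        assert bright.sum() == 50
        assert np.all(g[bright] == 200.0)


class TestComponents:
    def test_empty_mask_empty_list(self):
        assert seg.label_components(np.zeros((8, 8), bool)) == []

    def test_single_square(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        comps = seg.label_components(mask)
        assert len(comps) == 1
        assert comps[0].area == 100
        assert comps[0].bbox_aspect == pytest.approx(1.0)
        assert comps[0].centroid == pytest.approx((9.5, 9.5))

    def test_two_squares_ordered_by_area(self):
        mask = np.zeros((30, 30), bool)
        mask[2:6, 2:6] = True
        mask[10:20, 10:20] = True
        comps = seg.label_components(mask)
        assert [c.area for c in comps] == [100, 16]


class TestStructureRules:
    def _components(self, *boxes, shape=(100, 100)):
        mask = np.zeros(shape, bool)
        for r0, r1, c0, c1 in boxes:
            mask[r0:r1, c0:c1] = True
        return seg.label_components(mask)

    def test_central_triangle_survives_wide_bar_rejected(self):
        # central blob vs wide horizontal bar (aspect 10 > aspect_max 2)
        comps = self._components((40, 60, 45, 55), (10, 14, 20, 60))
        rules = seg.StructureRules(
            min_area_frac=0.005, centroid_zone=(0.25, 0.75, 0.25, 0.75), aspect_max=2.0
        )
        chosen = seg.apply_structure_rules(comps, rules, (100, 100))
        assert chosen is not None
        assert chosen.centroid == pytest.approx((49.5, 49.5))

    def test_upper_rectangle_survives_tall_bar_rejected(self):
        comps = self._components((10, 20, 30, 70), (30, 90, 48, 52))
        rules = seg.StructureRules(
            min_area_frac=0.005, centroid_zone=(0.0, 0.4, 0.05, 0.95), aspect_min=1.0
        )
        chosen = seg.apply_structure_rules(comps, rules, (100, 100))
        assert chosen is not None
        assert chosen.centroid[0] == pytest.approx(14.5)

    def test_empty_list_gives_none(self):
        rules = seg.StructureRules()
        assert seg.apply_structure_rules([], rules, (100, 100)) is None

    def test_invalid_rules_rejected(self):
        with pytest.raises(InvalidInputError):
            seg.StructureRules(aspect_min=3.0, aspect_max=2.0)


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((10, 10), bool)
        m[2:6, 2:6] = True
        assert seg.dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[0:2, 0:2] = True
        b[5:7, 5:7] = True
        assert seg.dice(a, b) == 0.0

    def test_partial_overlap_formula(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a[0:10, 0:10] = True  # 100 px
        b[2:12, 0:10] = True  # 100 px, overlap 80
        assert seg.dice(a, b) == pytest.approx(0.8)

    def test_both_empty_is_one(self):
        assert seg.dice(np.zeros((4, 4), bool), np.zeros((4, 4), bool)) == 1.0

    def test_symmetry_and_translation_invariance(self, rng):
        a = rng.random((16, 16)) > 0.6
        b = rng.random((16, 16)) > 0.6
        assert seg.dice(a, b) == seg.dice(b, a)
        assert seg.dice(np.roll(a, 3, 1), np.roll(b, 3, 1)) == pytest.approx(
            seg.dice(a, b)
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            seg.dice(np.zeros((4, 4), bool), np.zeros((5, 5), bool))


class TestSegmentGlottis:
    def test_phantom_recovery(self, compensated_image, default_sample):
        mask = seg.segment_glottis(compensated_image)
        assert seg.dice(mask, default_sample.truth.glottis) >= 0.85

    def test_no_dark_center_raises(self):
        img = np.full((64, 64, 3), 150, dtype=np.uint8)
        with pytest.raises(RegionNotFoundError):
            seg.segment_glottis(img)


class TestSegmentArytenoid:
    def test_phantom_recovery(self, compensated_image, default_sample):
        mask = seg.segment_arytenoid(compensated_image)
        assert seg.dice(mask, default_sample.truth.arytenoid) >= 0.85

    def test_snake_refinement_does_not_hurt(self):
        for sd in (2, 5, 8):
            s = make_phantom(PhantomParams(seed=sd))
            img = histogram_shift(s.image)
            refined, candidate = seg.segment_arytenoid(img, return_candidate=True)
            assert seg.dice(refined, s.truth.arytenoid) >= seg.dice(
                candidate, s.truth.arytenoid
            )

    def test_missing_arytenoid_raises(self):
        params = PhantomParams(seed=1)
        params.base_colors["arytenoid"] = params.base_colors["background"]
        img = histogram_shift(make_phantom(params).image)
        with pytest.raises(RegionNotFoundError):
            seg.segment_arytenoid(img)


class TestSegmentVocalCords:
    def test_phantom_recovery_both_sides(self, compensated_image, default_sample):
        glottis = seg.segment_glottis(compensated_image)
        left, right = seg.segment_vocal_cords(compensated_image, glottis)
        assert seg.dice(left, default_sample.truth.left_vc) >= 0.85
        assert seg.dice(right, default_sample.truth.right_vc) >= 0.85

    def test_mirror_swaps_left_right_exactly(self, compensated_image):
        glottis = seg.segment_glottis(compensated_image)
        left, right = seg.segment_vocal_cords(compensated_image, glottis)
        mirrored = compensated_image[:, ::-1].copy()
        m_glottis = seg.segment_glottis(mirrored)
        m_left, m_right = seg.segment_vocal_cords(mirrored, m_glottis)
        assert np.array_equal(m_left, right[:, ::-1])
        assert np.array_equal(m_right, left[:, ::-1])

    def test_n_star_in_window(self, compensated_image):
        glottis = seg.segment_glottis(compensated_image)
        _, (li, ri) = seg.segment_vocal_cords(
            compensated_image, glottis, return_info=True
        )
        assert 13 <= li.n_star <= 41
        assert 13 <= ri.n_star <= 41

    def test_masks_disjoint_from_glottis(self, compensated_image):
        glottis = seg.segment_glottis(compensated_image)
        left, right = seg.segment_vocal_cords(compensated_image, glottis)
        assert not np.any(left & glottis)
        assert not np.any(right & glottis)
        assert not np.any(left & right)

    def test_empty_glottis_rejected(self, compensated_image):
        with pytest.raises(InvalidInputError):
            seg.segment_vocal_cords(
                compensated_image, np.zeros(compensated_image.shape[:2], bool)
            )


class TestSegmentRegions:
    def test_all_regions_disjoint_and_nonempty(self, compensated_image):
        regions = seg.segment_regions(compensated_image)
        masks = list(regions.as_dict().values())
        for m in masks:
            assert m.sum() > 0
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                assert not np.any(masks[i] & masks[j])
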