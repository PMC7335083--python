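import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from laryq import features as feat
from laryq.compensation import histogram_shift
from laryq.errors import InvalidInputError
from laryq.phantom import LprEffect, PhantomParams, make_feature_cohort, make_phantom


def region(color, shape=(6, 6)):
    img = np.empty(shape + (3,), dtype=np.uint8)
    img[...] = color
    return img, np.ones(shape, bool)


class TestMeanChannel:
    def test_pure_red(self):
        img, mask = region((255, 0, 0))
        assert feat.mean_channel(img, mask, "R") == pytest.approx(255.0)
        assert feat.mean_channel(img, mask, "H") == pytest.approx(0.0)

    def test_pure_green_hue_120(self):
        img, mask = region((0, 255, 0))
        assert feat.mean_channel(img, mask, "H") == pytest.approx(120.0)

    def test_gray_region_neutral_chroma(self):
        img, mask = region((80, 80, 80))
        assert feat.mean_channel(img, mask, "Cb") == pytest.approx(128.0)
        assert feat.mean_channel(img, mask, "Cr") == pytest.approx(128.0)

    def test_circular_hue_mean_wraps(self):
        # hues 350 and 10 degrees average to 0, not 180
        img = np.zeros((1, 2, 3), dtype=np.uint8)
        img[0, 0] = (255, 0, 42)   # h ~ 350
        img[0, 1] = (255, 42, 0)   # h ~ 10
        h = feat.mean_channel(img, np.ones((1, 2), bool), "H")
        assert min(h, 360 - h) < 5.0

    def test_empty_mask_rejected(self):
        img, _ = region((10, 10, 10))
        with pytest.raises(InvalidInputError):
            feat.mean_channel(img, np.zeros((6, 6), bool), "R")


def brute_force_glcm(gray, mask, distance=1, levels=8):
    """Independent oracle: explicit pair enumeration."""
    q = (gray.astype(int) * levels) // 256
    counts = np.zeros((levels, levels))
    rows, cols = gray.shape
    for r in range(rows):
        for c in range(cols - distance):
            if mask[r, c] and mask[r, c + distance]:
                counts[q[r, c], q[r, c + distance]] += 1
                counts[q[r, c + distance], q[r, c]] += 1
    return counts / counts.sum()


def brute_force_stats(p):
    k = p.shape[0]
    eng = sum(p[i, j] ** 2 for i in range(k) for j in range(k))
    con = sum((i - j) ** 2 * p[i, j] for i in range(k) for j in range(k))
    hom = sum(p[i, j] / (1 + abs(i - j)) for i in range(k) for j in range(k))
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mi = sum(i * pi[i] for i in range(k))
    mj = sum(j * pj[j] for j in range(k))
    vi = sum((i - mi) ** 2 * pi[i] for i in range(k))
    vj = sum((j - mj) ** 2 * pj[j] for j in range(k))
    if vi <= 0 or vj <= 0:
        cor = 0.0
    else:
        cor = sum(
            (i - mi) * (j - mj) * p[i, j] for i in range(k) for j in range(k)
        ) / np.sqrt(vi * vj)
    return eng, con, cor, hom


class TestGlcm:
    def test_constant_region_single_entry(self):
        g = np.full((8, 8), 100, dtype=np.uint8)
        glcm = feat.glcm_matrix(g)
        assert np.count_nonzero(glcm.p) == 1
        assert glcm.p.sum() == pytest.approx(1.0)

    def test_checkerboard_hand_enumeration(self):
        # levels 0 and 1 alternate; the two horizontal pairs symmetrize to
        # p = [[0, .5], [.5, 0]]
        g = np.array([[0, 40], [40, 0]], dtype=np.uint8)
        glcm = feat.glcm_matrix(g, levels=8)
        assert glcm.p[0, 1] == pytest.approx(0.5)
        assert glcm.p[1, 0] == pytest.approx(0.5)
        assert feat.glcm_energy(glcm) == pytest.approx(0.5)
        assert feat.glcm_contrast(glcm) == pytest.approx(1.0)
        assert feat.glcm_homogeneity(glcm) == pytest.approx(0.5)

    def test_sums_to_one(self, rng):
        g = rng.integers(0, 256, size=(12, 12)).astype(np.uint8)
        mask = rng.random((12, 12)) > 0.3
        glcm = feat.glcm_matrix(g, mask)
        assert glcm.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_oracle_20_seeds(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            g = rng.integers(0, 256, size=(6, 6)).astype(np.uint8)
            mask = rng.random((6, 6)) > 0.3
            if not (mask[:, :-1] & mask[:, 1:]).any():
                continue
            glcm = feat.glcm_matrix(g, mask)
            oracle_p = brute_force_glcm(g, mask)
            assert np.allclose(glcm.p, oracle_p)
            eng, con, cor, hom = brute_force_stats(oracle_p)
            assert feat.glcm_energy(glcm) == pytest.approx(eng)
            assert feat.glcm_contrast(glcm) == pytest.approx(con)
            assert feat.glcm_correlation(glcm) == pytest.approx(cor)
            assert feat.glcm_homogeneity(glcm) == pytest.approx(hom)

    def test_constant_region_stats_extremes(self):
        g = np.full((16, 16), 33, dtype=np.uint8)
        glcm = feat.glcm_matrix(g)
        assert feat.glcm_energy(glcm) == pytest.approx(1.0)
        assert feat.glcm_contrast(glcm) == pytest.approx(0.0)
        assert feat.glcm_homogeneity(glcm) == pytest.approx(1.0)

    def test_contrast_within_bounds(self, rng):
        g = rng.integers(0, 256, size=(10, 10)).astype(np.uint8)
        glcm = feat.glcm_matrix(g, levels=8)
        assert 0.0 <= feat.glcm_contrast(glcm) <= 49.0
        assert 0.0 <= feat.glcm_energy(glcm) <= 1.0

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(InvalidInputError):
            feat.glcm_energy(np.ones((8, 8)))

    def test_no_valid_pair_rejected(self):
        g = np.zeros((4, 4), dtype=np.uint8)
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = True
        with pytest.raises(InvalidInputError):
            feat.glcm_matrix(g, mask)


class TestExtractFeatures:
    def test_vector_length_and_names(self, compensated_image, default_sample):
        vec = feat.extract_features(compensated_image, default_sample.truth)
        assert len(vec) == 36
        assert list(vec.index) == list(feat.FEATURE_NAMES)
        assert 0.0 <= vec["A_eng"] <= 1.0
        assert vec["VC_con max"] >= vec["VC_con min"]

    def test_red_shift_increases_vc_r_max(self):
        from dataclasses import replace

        base = PhantomParams(seed=7)
        s0 = make_phantom(base)
        s1 = make_phantom(replace(base, lpr=True, lpr_effect=LprEffect(vc_red_shift=25.0)))
        v0 = feat.extract_features(s0.image, s0.truth)
        v1 = feat.extract_features(s1.image, s1.truth)
        assert v1["VC_R max"] > v0["VC_R max"]

    def test_hue_features_invariant_to_luma_shift(self, default_sample):
        s = default_sample
        v0 = feat.extract_features(s.image, s.truth)
        v1 = feat.extract_features(histogram_shift(s.image), s.truth)
        for name in ("A_Cb", "A_Cr", "VC_Cb max", "VC_Cr min"):
            assert v1[name] == pytest.approx(v0[name], abs=1.5)

    def test_empty_region_named_in_error(self, default_sample):
        broken = type(default_sample.truth)(
            glottis=default_sample.truth.glottis,
            left_vc=np.zeros_like(default_sample.truth.left_vc),
            right_vc=default_sample.truth.right_vc,
            arytenoid=default_sample.truth.arytenoid,
        )
        with pytest.raises(InvalidInputError, match="left_vc"):
            feat.extract_features(default_sample.image, broken)


class TestFisher:
    def test_identical_distributions_zero(self):
        vals = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        labels = np.array(["a"] * 3 + ["b"] * 3)
        assert feat.fisher_score(vals, labels) == 0.0

    def test_known_value(self):
        # class means 0 and 2, sample variances exactly 1 each -> 4/2 = 2
        d = np.sqrt(0.5)
        vals = np.array([-d, d, 2 - d, 2 + d])
        labels = np.array(["a", "a", "b", "b"])
        assert feat.fisher_score(vals, labels) == pytest.approx(2.0)

    @given(
        a=st.floats(min_value=0.1, max_value=10.0),
        b=st.floats(min_value=-50.0, max_value=50.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, 40)
        vals[20:] += 1.5
        labels = np.array(["x"] * 20 + ["y"] * 20)
        f0 = feat.fisher_score(vals, labels)
        f1 = feat.fisher_score(a * vals + b, labels)
        assert f1 == pytest.approx(f0, rel=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            feat.fisher_score(np.arange(4.0), np.array(["a"] * 4))


class TestRankFeatures:
    def test_planted_effect_ranks_first(self):
        table, labels, _ = make_feature_cohort(150, 150, effect={"A_Cb": 2.0}, seed=4)
        scores, selected = feat.rank_features(table, labels, top_k=1)
        assert scores[0].feature == "A_Cb"
        assert selected == ["A_Cb"]

    def test_null_cohort_scores_small(self):
        table, labels, _ = make_feature_cohort(200, 200, effect=0.0, seed=5)
        scores, _ = feat.rank_features(table, labels)
        assert scores[0].f < 0.05

    def test_top_k_36_returns_all(self):
        table, labels, _ = make_feature_cohort(30, 30, seed=6)
        scores, selected = feat.rank_features(table, labels, top_k=36)
        assert len(selected) == 36

    def test_default_selection_flag(self):
        table, labels, _ = make_feature_cohort(30, 30, seed=7)
        _, selected = feat.rank_features(
            table, labels, use_default_selection=True
        )
        assert selected == list(feat.SELECTED_FEATURES)

    def test_missing_column_rejected(self):
        table, labels, _ = make_feature_cohort(10, 10, seed=8)
        with pytest.raises(InvalidInputError):
            feat.rank_features(table.drop(columns=["A_R"]), labels)
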