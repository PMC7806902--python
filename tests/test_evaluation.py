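import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uvsynth import evaluation as E


class TestPerPixelL1:
    def test_identical_images_zero(self, rng):
        img = rng.random((32, 32))
        assert E.per_pixel_l1(img, img) == 0.0

    def test_median_and_mean_on_known_distances(self):
        a = np.zeros(3)
        b = np.array([0.0, 10.0, 255.0]) / 255.0
        assert E.per_pixel_l1(a, b, aggregate="median") == pytest.approx(10.0)
        assert E.per_pixel_l1(a, b, aggregate="mean") == pytest.approx(88.0 + 1 / 3)

    def test_permutation_invariance(self, rng):
        a, b = rng.random(100), rng.random(100)
        perm = rng.permutation(100)
        for agg in ("median", "mean"):
            assert E.per_pixel_l1(a, b, aggregate=agg) == pytest.approx(
                E.per_pixel_l1(a[perm], b[perm], aggregate=agg))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            E.per_pixel_l1(np.zeros((4, 4)), np.zeros((4, 4)),
                           mask=np.zeros((4, 4), bool))

    def test_mask_restricts_pixels(self):
        a = np.zeros((2, 2))
        b = np.array([[1.0, 0.0], [0.0, 0.0]])
        mask = np.array([[True, False], [False, False]])
        assert E.per_pixel_l1(a, b, mask=mask) == pytest.approx(255.0)


class TestFid:
    def test_identical_sets_zero(self, rng):
        f = rng.random((20, 5))
        assert E.fid(f, f) == pytest.approx(0.0, abs=1e-8)

    def test_point_masses_reduce_to_squared_mean_distance(self):
        a = np.zeros((3, 1))
        b = np.ones((3, 1))
        assert E.fid(a, b) == pytest.approx(1.0, abs=1e-12)

    def test_one_dimensional_closed_form(self):
        # mu = (0, 1), sigma^2 = (1, 4):  1 + (1 + 4 - 2*2) = 2
        a = np.array([[-np.sqrt(0.5)], [np.sqrt(0.5)]])
        b = np.array([[1 - np.sqrt(2.0)], [1 + np.sqrt(2.0)]])
        assert E.fid(a, b) == pytest.approx(2.0, abs=1e-10)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_symmetry_and_nonnegativity(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(12, 4))
        b = rng.normal(size=(15, 4)) + rng.normal(size=4)
        ab, ba = E.fid(a, b), E.fid(b, a)
        assert ab >= 0.0
        assert ab == pytest.approx(ba, abs=1e-8)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_univariate_closed_form(self, seed):
        """For 1-D features FID = (mu1-mu2)^2 + (s1 - s2)^2 with s the
        standard deviations."""
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(30, 1))
        b = 2.0 * rng.normal(size=(40, 1)) + 1.0
        expected = (a.mean() - b.mean()) ** 2 + (a.std(ddof=1) - b.std(ddof=1)) ** 2
        assert E.fid(a, b) == pytest.approx(float(expected), abs=1e-9)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            E.fid(rng.random((5, 3)), rng.random((5, 4)))

    def test_single_vector_rejected(self, rng):
        with pytest.raises(ValueError):
            E.fid(rng.random((1, 3)), rng.random((5, 3)))


class TestEmbedPatches:
    def test_deterministic_features(self, clean_pair):
        emb = E.RandomProjectionEmbedder(seed=7)
        f1 = E.embed_patches([clean_pair.uv], [clean_pair.face_mask], emb,
                             patch_size=64)
        f2 = E.embed_patches([clean_pair.uv], [clean_pair.face_mask], emb,
                             patch_size=64)
        np.testing.assert_array_equal(f1, f2)
        assert E.fid(f1, f2) == pytest.approx(0.0, abs=1e-8)

    def test_spot_load_separates_cohorts(self):
        """FID(spotless, heavy-spot) exceeds FID(spotless, spotless')."""
        from uvsynth import synthetic_skin as S

        emb = E.RandomProjectionEmbedder(seed=0)

        def feats(n_spots, seed):
            p = S.PhantomParams(seed=seed, n_spots=n_spots, misalign_max=0)
            pairs = S.make_cohort(6, p)
            return E.embed_patches([q.uv for q in pairs],
                                   [q.face_mask for q in pairs], emb,
                                   patch_size=64)
        spotless_a = feats(0, 1)
        spotless_b = feats(0, 2)
        heavy = feats(60, 3)
        assert E.fid(spotless_a, heavy) > E.fid(spotless_a, spotless_b)

    def test_no_covering_patches_rejected(self, rng):
        img = rng.random((64, 64))
        with pytest.raises(ValueError):
            E.embed_patches([img], [np.zeros((64, 64), bool)],
                            E.RandomProjectionEmbedder(), patch_size=64)


class TestMaskMetrics:
    def test_perfect_prediction(self):
        t = np.zeros((10, 10), bool)
        t[2:5, 2:5] = True
        m = E.mask_metrics(t, t)
        assert m == {"iou": 1.0, "recall": 1.0, "precision": 1.0, "f": 1.0}

    def test_partial_overlap_arithmetic(self):
        truth = np.zeros(200, bool)
        truth[:100] = True
        pred = np.zeros(200, bool)
        pred[75:125] = True               # 50 predicted, 25 overlap
        m = E.mask_metrics(pred, truth)
        assert m["iou"] == pytest.approx(25 / 125)
        assert m["recall"] == pytest.approx(0.25)
        assert m["precision"] == pytest.approx(0.5)
        assert m["f"] == pytest.approx(1 / 3)

    def test_disjoint_masks_all_zero(self):
        t = np.zeros(10, bool)
        t[:3] = True
        p = np.zeros(10, bool)
        p[5:] = True
        m = E.mask_metrics(p, t)
        assert m["iou"] == 0 and m["recall"] == 0 and m["precision"] == 0
        assert m["f"] == 0

    def test_empty_truth_conventions(self):
        empty = np.zeros(10, bool)
        assert E.mask_metrics(empty, empty)["iou"] == 1.0
        pred = np.ones(10, bool)
        m = E.mask_metrics(pred, empty)
        assert m["iou"] == 0.0 and m["precision"] == 0.0
        assert np.isnan(m["recall"])

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_f_harmonic_mean_and_iou_bound(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.random((16, 16)) < 0.3
        p = rng.random((16, 16)) < 0.3
        m = E.mask_metrics(p, t)
        if t.any() and m["precision"] + m["recall"] > 0:
            assert m["f"] == pytest.approx(
                2 * m["precision"] * m["recall"]
                / (m["precision"] + m["recall"]))
            assert m["iou"] <= min(m["precision"], m["recall"]) + 1e-12


class TestCorrelationRegression:
    def test_exact_linear_relations(self):
        assert E.pearson([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert E.pearson([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert E.pearson([1, 2, 3], [1, 2, 4]) == pytest.approx(
            9 / np.sqrt(84), abs=1e-12)

    def test_no_intercept_slope(self):
        assert E.regress_no_intercept([1, 2], [2, 4]) == pytest.approx(2.0)
        assert E.regress_no_intercept([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert E.regress_no_intercept([1, 2], [1, 1]) == pytest.approx(0.6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            E.pearson([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            E.pearson([1, 2], [1, 2])
        with pytest.raises(ValueError):
            E.regress_no_intercept([0, 0], [1, 2])

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_agree_with_direct_summation_oracle(self, seed):
        """Both statistics match naive direct-summation formulas to 1e-12."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 40))
        x = rng.normal(size=n) * 10 + 1
        y = 0.8 * x + rng.normal(size=n)
        sx, sy = x.sum(), y.sum()
        sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
        r_oracle = ((n * sxy - sx * sy)
                    / np.sqrt((n * sxx - sx ** 2) * (n * syy - sy ** 2)))
        assert E.pearson(x, y) == pytest.approx(r_oracle, abs=1e-12)
        assert E.regress_no_intercept(x, y) == pytest.approx(sxy / sxx, abs=1e-12)


class TestHeatmapAndReport:
    def test_heatmap_values_and_masking(self, rng):
        a = rng.random((16, 16))
        b = rng.random((16, 16))
        mask = np.zeros((16, 16), bool)
        mask[:8] = True
        hm, overlay = E.l1_heatmap(a, b, mask)
        np.testing.assert_allclose(hm[:8], np.abs(a - b)[:8] * 255.0)
        assert (hm[8:] == 0).all()
        assert overlay.shape == (16, 16, 4)
        hm0, _ = E.l1_heatmap(a, a)
        assert (hm0 == 0).all()

    def test_ablation_report_structure(self):
        metrics = {("uv_net", "+", "+"): {"l1": 5.0, "fid": 1.0},
                   ("grayscale", "-", "-"): {"l1": 40.0, "fid": 9.0}}
        df = E.ablation_report(metrics)
        assert len(df) == 8
        assert df.loc[0, "median_l1"] == 5.0
        assert df["median_l1"].dropna().ge(0).all()
        assert np.isnan(df.loc[1, "fid"])   # missing variant reported NA
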