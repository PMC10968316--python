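import numpy as np
import pytest

from mrmotionsim.metrics import (cc, cnr, cov_background, evaluate_pairs,
                                 kmeans_segment, paired_ttest, psnr, rmse, uqi)


class TestRMSE:
    def test_identity_is_zero(self):
        f = np.arange(9.0).reshape(3, 3)
        assert rmse(f, f) == 0.0

    @pytest.mark.parametrize("f,g,expected", [
        ([0.0, 0.0], [1.0, 1.0], 1.0),
        ([0.0, 1.0], [1.0, 1.0], np.sqrt(0.5)),
    ])
    def test_hand_computed_values(self, f, g, expected):
        assert rmse(np.array(f), np.array(g)) == pytest.approx(expected)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse(np.zeros((2, 2)), np.zeros((3, 3)))


class TestPSNR:
    def test_rmse_equal_to_peak_gives_zero_db(self):
        f = np.array([1.0, 1.0])
        g = np.array([0.0, 0.0])  # rmse 1, peak 1
        assert psnr(f, g) == pytest.approx(0.0)

    def test_halving_rmse_adds_6db(self):
        f = np.array([1.0, 0.0, 1.0, 0.0])
        g1 = f + 0.2
        g2 = f + 0.1
        assert psnr(f, g2, s_peak=1.0) - psnr(f, g1, s_peak=1.0) == \
            pytest.approx(20 * np.log10(2))

    def test_closed_form_value(self):
        f = np.array([1.0, 1.0])
        g = np.array([0.9, 1.1])  # rmse 0.1
        assert psnr(f, g, s_peak=1.0) == pytest.approx(20.0)

    def test_identical_images_give_inf_sentinel(self):
        f = np.array([1.0, 2.0])
        assert psnr(f, f) == np.inf

    def test_monotone_decreasing_in_rmse(self):
        f = np.ones(16)
        vals = [psnr(f, f + eps, s_peak=1.0) for eps in (0.01, 0.02, 0.05, 0.3)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestCC:
    def test_identity_and_affine_invariance(self):
        rng = np.random.default_rng(0)
        f = rng.random((5, 5))
        assert cc(f, f) == pytest.approx(1.0)
        assert cc(f, 3.0 * f + 2.0) == pytest.approx(1.0)
        assert cc(f, -f) == pytest.approx(-1.0)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            cc(np.ones((3, 3)), np.zeros((3, 3)) + np.eye(3))


class TestUQI:
    def test_identity_is_one(self):
        rng = np.random.default_rng(1)
        f = rng.random((6, 6)) + 0.5
        assert uqi(f, f) == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            f, g = rng.random((4, 4)), rng.random((4, 4))
            assert uqi(f, g) == pytest.approx(uqi(g, f))

    def test_hand_computed_value(self):
        f = np.array([1.0, 2.0, 3.0, 4.0])
        g = np.array([1.0, 2.0, 3.0, 5.0])
        # direct evaluation of 4*mu_f*mu_g*cov / ((mu_f^2+mu_g^2)(var_f+var_g))
        mu_f, mu_g = f.mean(), g.mean()
        cov = np.mean((f - mu_f) * (g - mu_g))
        expected = 4 * mu_f * mu_g * cov / ((mu_f**2 + mu_g**2) * (f.var() + g.var()))
        assert uqi(f, g) == pytest.approx(expected)
        assert uqi(f, g) < 1.0

    def test_optimum_iff_equal(self):
        rng = np.random.default_rng(3)
        f = rng.random((8, 8)) + 0.5
        assert uqi(f, f) == pytest.approx(1.0)
        assert uqi(f, f + rng.random((8, 8)) * 0.5) < 1.0 - 1e-6


class TestSegmentation:
    def test_two_value_image_exact(self):
        img = np.zeros((10, 10))
        img[:, 5:] = 1.0
        labels = kmeans_segment(img, k=2, seed=0)
        np.testing.assert_array_equal(labels, img.astype(int))

    def test_phantom_slice_recovery(self, small_phantom):
        z = 4
        img = small_phantom.volume.get_slice(z)
        truth = small_phantom.labels[:, :, z]
        # map truth labels to intensity rank (k-means labels are rank-ordered)
        rank = np.argsort(np.argsort(small_phantom.class_means))
        labels = kmeans_segment(img, k=4, seed=0)
        agreement = np.mean(labels == rank[truth])
        assert agreement >= 0.99

    def test_deterministic(self, small_phantom):
        img = small_phantom.volume.get_slice(2)
        a = kmeans_segment(img, k=4, seed=3)
        b = kmeans_segment(img, k=4, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError):
            kmeans_segment(np.ones((4, 4)), k=2, seed=0)


class TestReferenceFree:
    def test_cov_constant_background_is_zero(self):
        img = np.full((4, 4), 3.0)
        assert cov_background(img, np.ones((4, 4), bool)) == 0.0

    def test_cov_hand_value_population_sd(self):
        img = np.array([[1.0, 3.0]])
        assert cov_background(img, np.ones((1, 2), bool)) == pytest.approx(0.5)

    def test_cov_scale_invariant(self):
        rng = np.random.default_rng(4)
        img = rng.random((5, 5)) + 1.0
        mask = np.ones((5, 5), bool)
        assert cov_background(img, mask) == pytest.approx(
            cov_background(7.3 * img, mask))

    def test_cnr_hand_value(self):
        # tissue mean 10 sd 3; background mean 2 sd 4 -> (10-2)/5 = 1.6
        img = np.array([7.0, 13.0, -2.0, 6.0])
        t_mask = np.array([True, True, False, False])
        b_mask = ~t_mask
        assert cnr(img, t_mask, b_mask) == pytest.approx(1.6)

    def test_cnr_zero_when_means_equal(self):
        img = np.array([1.0, 3.0, 1.0, 3.0])
        assert cnr(img, np.array([1, 1, 0, 0], bool),
                   np.array([0, 0, 1, 1], bool)) == 0.0

    def test_cnr_shift_invariant(self):
        rng = np.random.default_rng(5)
        img = rng.random((6, 6))
        t = np.zeros((6, 6), bool); t[:3] = True
        assert cnr(img, t, ~t) == pytest.approx(cnr(img + 11.0, t, ~t))


class TestPairedTTest:
    def test_equal_sequences_give_zero_t(self):
        a = [1.0, 2.0, 3.0]
        assert paired_ttest(a, a) == (0.0, 1.0)

    def test_closed_form_t(self):
        a = np.array([1.0, 1.0, 1.0, 2.0])
        b = np.zeros(4)
        d = a - b
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        t, p = paired_ttest(a, b)
        assert t == pytest.approx(expected_t)
        assert 0 < p <= 1


class TestEvaluatePairs:
    def test_identical_comparisons(self):
        rng = np.random.default_rng(6)
        refs = [rng.random((8, 8)) + 0.2 for _ in range(3)]
        report = evaluate_pairs(refs, refs)
        assert report.aggregate["rmse"] == (0.0, 0.0)
        assert report.aggregate["uqi"] == (pytest.approx(1.0), pytest.approx(0.0))
        assert report.aggregate["cc"] == (pytest.approx(1.0), pytest.approx(0.0))
        assert report.n_infinite_psnr == 3

    def test_single_pair_sd_is_zero(self):
        rng = np.random.default_rng(7)
        f = rng.random((8, 8))
        report = evaluate_pairs([f], [f + 0.1 * rng.random((8, 8))])
        for mean, sd in report.aggregate.values():
            assert sd == 0.0

    def test_aggregate_matches_independent_recomputation(self):
        rng = np.random.default_rng(8)
        refs = [rng.random((8, 8)) + 0.2 for _ in range(5)]
        comps = [r + 0.05 * rng.random((8, 8)) for r in refs]
        report = evaluate_pairs(refs, comps)
        manual = np.mean([rmse(f, g) for f, g in zip(refs, comps)])
        assert report.aggregate["rmse"][0] == pytest.approx(manual)

    def test_two_methods_yield_ttests(self):
        rng = np.random.default_rng(9)
        refs = [rng.random((8, 8)) + 0.2 for _ in range(4)]
        c1 = [r + 0.1 * rng.random((8, 8)) for r in refs]
        c2 = [r + 0.01 * rng.random((8, 8)) for r in refs]
        report = evaluate_pairs(refs, c1, comparisons2=c2)
        assert set(report.ttests) == {"rmse", "psnr", "uqi", "cc"}
        t, p = report.ttests["rmse"]
        assert np.isfinite(t) and 0 < p <= 1
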