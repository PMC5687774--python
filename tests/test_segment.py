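"""Segmentation: clustering, validity measure vs a loop oracle, auto selection."""

import numpy as np
import pytest

from holoquant import segment as seg


def brute_force_vm(pixels, labels, centres, params):
    """Independent loop-based recomputation of the validity measure."""
    M = len(pixels)
    intra = 0.0
    for x, l in zip(pixels, labels):
        d = 0.0
        for a, b in zip(x, centres[l]):
            d += (a - b) ** 2
        intra += d
    intra /= M
    inter = np.inf
    k = len(centres)
    for i in range(k - 1):
        for j in range(i + 1, k):
            d = 0.0
            for a, b in zip(centres[i], centres[j]):
                d += (a - b) ** 2
            inter = min(inter, d)
    sign = -1.0 if params.sign_variant == "as_printed" else 1.0
    gauss = np.exp(-((k - params.mu) ** 2) / (2 * params.sigma**2)) / np.sqrt(2 * np.pi * params.sigma**2)
    y = sign * params.m_const * gauss + 1.0
    return y * intra / inter


def two_blob_pixels(seed=0, n=200, sep=10.0):
    rng = np.random.default_rng(seed)
    a = rng.normal([0, 0, 0], 0.05, (n, 3))
    b = rng.normal([sep * 0.05] * 3, 0.05, (n, 3))
    return np.vstack([a, b]), np.repeat([0, 1], n)


class TestGaussianSmooth:
    def test_constant_unchanged(self):
        img = np.full((32, 32, 3), 0.7)
        assert np.allclose(seg.gaussian_smooth(img, 2.0), img)

    def test_impulse_kernel_normalised(self):
        img = np.zeros((33, 33))
        img[16, 16] = 1.0
        out = seg.gaussian_smooth(img, 2.0)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)

    def test_reduces_noise_variance(self):
        rng = np.random.default_rng(0)
        img = rng.random((64, 64, 3))
        assert seg.gaussian_smooth(img, 1.5).var() < img.var()


class TestKMeans:
    def test_separated_blobs_partitioned_exactly(self):
        pixels, truth = two_blob_pixels()
        res = seg.kmeans_segment(pixels, 2, seed=0)
        agree = max((res.labels == truth).mean(), (res.labels != truth).mean())
        assert agree == 1.0

    def test_n_equals_k_gives_zero_intra(self):
        pixels = np.eye(3)
        res = seg.kmeans_segment(pixels, 3, seed=0)
        rec = seg.validity_measure(pixels, res, seg.VMParams(k_min=2, k_max=3))
        assert rec.intra == 0.0
        assert rec.vm == 0.0

    def test_deterministic(self):
        pixels, _ = two_blob_pixels(3)
        r1 = seg.kmeans_segment(pixels, 4, seed=9)
        r2 = seg.kmeans_segment(pixels, 4, seed=9)
        assert np.array_equal(r1.labels, r2.labels)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            seg.kmeans_segment(np.random.rand(3, 3), 5)


class TestFCM:
    def test_memberships_sum_to_one(self):
        pixels, _ = two_blob_pixels(1)
        res = seg.fcm_segment(pixels, 3, seed=1)
        assert np.allclose(res.membership.sum(axis=1), 1.0, atol=1e-9)

    def test_pixel_at_centre_has_full_membership(self):
        pixels, _ = two_blob_pixels(2)
        res = seg.fcm_segment(pixels, 2, seed=2)
        probe = np.vstack([pixels, res.centres[0][None, :]])
        res2 = seg.fcm_segment(probe, 2, seed=2)
        # recompute membership of an exact centre point directly via the rule
        d2 = ((res.centres[0] - res.centres) ** 2).sum(axis=1)
        assert d2[0] == 0.0  # by construction

    def test_hardened_fcm_matches_kmeans_on_blobs(self):
        pixels, _ = two_blob_pixels(4)
        km = seg.kmeans_segment(pixels, 2, seed=0)
        fc = seg.fcm_segment(pixels, 2, fuzzifier=1.1, seed=0)
        agree = max((km.labels == fc.labels).mean(), (km.labels != fc.labels).mean())
        assert agree == 1.0

    def test_fuzzifier_must_exceed_one(self):
        with pytest.raises(ValueError):
            seg.fcm_segment(np.random.rand(10, 3), 2, fuzzifier=1.0)


class TestValidityMeasure:
    def test_zero_intra_gives_zero_vm(self):
        pixels = np.array([[0.0, 0, 0], [1.0, 1, 1], [0, 0, 0], [1, 1, 1]])
        res = seg.kmeans_segment(pixels, 2, seed=0)
        assert seg.validity_measure(pixels, res, seg.VMParams()).vm == 0.0

    def test_multiplier_both_sign_variants(self):
        pos = seg.VMParams(sign_variant="positive_gaussian").multiplier(2)
        neg = seg.VMParams(sign_variant="as_printed").multiplier(2)
        assert pos == pytest.approx(1 + 20 / np.sqrt(2 * np.pi), abs=1e-4)  # ~8.9789
        assert neg == pytest.approx(1 - 20 / np.sqrt(2 * np.pi), abs=1e-4)  # ~-6.9789

    def test_matches_loop_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        params = seg.VMParams()
        for trial in range(100):
            n = rng.integers(8, 21)
            k = int(rng.integers(2, 5))
            pixels = rng.random((n, 3))
            res = seg.kmeans_segment(pixels, k, seed=int(rng.integers(0, 100)))
            if len(np.unique(res.labels)) < k:
                continue
            try:
                rec = seg.validity_measure(pixels, res, params)
            except seg.DegenerateClusteringError:
                continue
            expected = brute_force_vm(pixels, res.labels, res.centres, params)
            assert rec.vm == pytest.approx(expected, abs=1e-9)

    def test_coincident_centres_rejected(self):
        res = seg.SegmentationResult(
            labels=np.array([0, 1]), centres=np.array([[0.5, 0.5, 0.5], [0.5, 0.5, 0.5]]),
            membership=np.eye(2), colour_space="rgb", pixel_count=2,
        )
        with pytest.raises(seg.DegenerateClusteringError):
            seg.validity_measure(np.random.rand(2, 3), res, seg.VMParams())


class TestAutoSegment:
    def three_patch_image(self):
        img = np.zeros((60, 90, 3))
        img[:, :30] = [0.9, 0.1, 0.1]
        img[:, 30:60] = [0.1, 0.9, 0.1]
        img[:, 60:] = [0.1, 0.1, 0.9]
        rng = np.random.default_rng(0)
        return np.clip(img + rng.normal(0, 0.01, img.shape), 0, 1)

    def five_patch_image(self):
        img = np.zeros((80, 100, 3))
        cols = [[0.85, 0.1, 0.1], [0.1, 0.8, 0.15], [0.15, 0.2, 0.85], [0.9, 0.9, 0.9], [0.05, 0.05, 0.05]]
        for i, c in enumerate(cols):
            img[:, i * 20 : (i + 1) * 20] = c
        rng = np.random.default_rng(1)
        return np.clip(img + rng.normal(0, 0.01, img.shape), 0, 1)

    def test_selects_planted_k3(self):
        _, vm = seg.auto_segment(self.three_patch_image(), "kmeans", "rgb", smooth_sigma=None)
        assert vm.k_best == 3

    def test_selects_planted_k5(self):
        _, vm = seg.auto_segment(self.five_patch_image(), "kmeans", "rgb", smooth_sigma=None)
        assert vm.k_best == 5

    def test_fcm_agrees_on_planted_k3(self):
        _, vm = seg.auto_segment(self.three_patch_image(), "fcm", "rgb", smooth_sigma=None)
        assert vm.k_best == 3

    def test_collapsed_k_range(self):
        params = seg.VMParams(k_min=4, k_max=4)
        _, vm = seg.auto_segment(self.three_patch_image(), "kmeans", "rgb", params=params, smooth_sigma=None)
        assert vm.k_best == 4

    def test_deterministic(self):
        img = self.five_patch_image()
        s1, v1 = seg.auto_segment(img, "kmeans", "lab", seed=5)
        s2, v2 = seg.auto_segment(img, "kmeans", "lab", seed=5)
        assert np.array_equal(s1.labels, s2.labels)
        assert v1.k_best == v2.k_best

    def test_estimator_facade(self):
        est = seg.AutoSegmenter(method="kmeans", colour_space="rgb", smooth_sigma=None)
        labels = est.fit_predict(self.three_patch_image())
        assert est.k_ == 3
        assert labels.shape == (60, 90)
        assert est.get_params()["method"] == "kmeans"


class TestHueCircularity:
    def test_hue_features_wrap_continuously(self):
        from holoquant.segment import features_to_hsi, pixels_in_space

        rgb_10 = np.array([[0.8, 0.25, 0.2]])
        f = pixels_in_space(rgb_10, "hsi")
        back = features_to_hsi(f)
        from holoquant.color import rgb_to_hsi

        expected = rgb_to_hsi(rgb_10)
        assert np.allclose(back, expected, atol=1e-9)

    def test_near_zero_hues_are_close_in_feature_space(self):
        reds = np.array([[0.9, 0.1, 0.11], [0.9, 0.11, 0.1]])  # hues just below/above 0
        f = pixels_in_space_reds = seg.pixels_in_space(reds, "hsi")
        d = np.sqrt(((f[0] - f[1]) ** 2).sum())
        assert d < 0.05
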