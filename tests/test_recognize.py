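"""Recognition: separability vs loop oracle, descriptors, SOM classification."""

import numpy as np
import pytest

from holoquant import recognize as rec
from holoquant.color import linear_rgb_to_xyz


def brute_force_J(X, y):
    """Explicit-sum Fisher separability, written independently of the package."""
    classes = sorted(set(y.tolist()))
    d = X.shape[1]
    Sw = np.zeros((d, d))
    means, sizes = [], []
    for c in classes:
        rows = [x for x, l in zip(X, y) if l == c]
        m = sum(rows) / len(rows)
        for x in rows:
            dev = (x - m).reshape(-1, 1)
            Sw += dev @ dev.T
        means.append(m)
        sizes.append(len(rows))
    N = sum(sizes)
    grand = sum(s * m for s, m in zip(sizes, means)) / N
    Sb = np.zeros((d, d))
    for s, m in zip(sizes, means):
        dev = (m - grand).reshape(-1, 1)
        Sb += s * (dev @ dev.T)
    return float(np.trace(np.linalg.inv(Sw) @ Sb))


class TestSeparability:
    def test_equal_means_give_zero(self):
        X = np.array([[1.0], [3.0], [1.0], [3.0]])
        y = np.array([0, 0, 1, 1])
        assert rec.separability(X, y).J == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_1d_example(self):
        X = np.array([[1.0], [3.0], [5.0], [7.0]])
        y = np.array([0, 0, 1, 1])
        rep = rec.separability(X, y)
        assert rep.Sw[0, 0] == pytest.approx(4.0)
        assert rep.Sb[0, 0] == pytest.approx(16.0)
        assert rep.J == pytest.approx(4.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.random((30, 3))
        y = rng.integers(0, 3, 30)
        J1 = rec.separability(X, y).J
        J2 = rec.separability(X + np.array([5.0, -2.0, 11.0]), y).J
        assert J1 == pytest.approx(J2, rel=1e-9)

    def test_matches_loop_oracle_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(8, 31))
            d = int(rng.integers(1, 4))
            c = int(rng.integers(2, 5))
            X = rng.random((n, d))
            y = rng.integers(0, c, n)
            if np.unique(y).size < 2 or any((y == cl).sum() < d + 1 for cl in np.unique(y)):
                continue
            try:
                ours = rec.separability(X, y).J
            except rec.SingularScatterError:
                continue
            assert ours == pytest.approx(brute_force_J(X, y), abs=1e-9)

    def test_scatter_matrices_are_psd(self):
        rng = np.random.default_rng(2)
        X = rng.random((40, 3))
        y = rng.integers(0, 4, 40)
        rep = rec.separability(X, y)
        assert np.all(np.linalg.eigvalsh(rep.Sw) > -1e-12)
        assert np.all(np.linalg.eigvalsh(rep.Sb) > -1e-12)
        assert rep.class_sizes.sum() == rep.total

    def test_singular_scatter_reported(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 4.0], [3.0, 4.0]])  # no within-class spread
        y = np.array([0, 0, 1, 1])
        with pytest.raises(rec.SingularScatterError):
            rec.separability(X, y)

    def test_literal_product_variant_available(self):
        X = np.array([[1.0], [3.0], [5.0], [7.0]])
        y = np.array([0, 0, 1, 1])
        assert rec.separability(X, y, variant="literal_product").J == pytest.approx(64.0)


class TestDescriptor:
    def test_flat_segment_reproduces_colour(self):
        rgb = np.full((10, 10, 3), [0.2, 0.6, 0.4])
        xyz = linear_rgb_to_xyz(rgb)
        labels = np.zeros((10, 10), dtype=int)
        d = rec.extract_descriptor(xyz, rgb, labels, 0)
        from holoquant.color import rgb_to_hsi, xyz_to_lab

        expected = np.concatenate([
            [0.2, 0.6, 0.4], rgb_to_hsi(np.array([0.2, 0.6, 0.4])), xyz_to_lab(xyz[0, 0])
        ])
        assert np.allclose(d.vector, expected, atol=1e-9)
        assert d.pixel_count == 100

    def test_hue_averaged_circularly(self):
        import colorsys

        a = np.array(colorsys.hsv_to_rgb(10 / 360, 0.9, 0.9))
        b = np.array(colorsys.hsv_to_rgb(350 / 360, 0.9, 0.9))
        rgb = np.stack([np.tile(a, (4, 1)), np.tile(b, (4, 1))]).reshape(2, 4, 3)
        xyz = linear_rgb_to_xyz(rgb)
        labels = np.zeros((2, 4), dtype=int)
        d = rec.extract_descriptor(xyz, rgb, labels, 0)
        hue = d.vector[3]
        assert min(hue, 360 - hue) < 2.0  # near 0, never near 180

    def test_empty_segment_rejected(self):
        rgb = np.zeros((4, 4, 3))
        with pytest.raises(ValueError):
            rec.extract_descriptor(rgb, rgb, np.zeros((4, 4), int), segment_id=3)


def gaussian_classes(seed=0, n=200, sep=6.0, d=9):
    rng = np.random.default_rng(seed)
    mu = np.zeros(d)
    mu2 = mu.copy()
    mu2[:3] = sep  # 6 sigma separation on three axes
    X = np.vstack([rng.normal(mu, 1.0, (n // 2, d)), rng.normal(mu2, 1.0, (n // 2, d))])
    y = np.array(["background"] * (n // 2) + ["hologram"] * (n // 2))
    return X, y


class TestSOM:
    def test_separated_classes_classified_holdout(self):
        X, y = gaussian_classes(seed=1)
        som = rec.SOMClassifier(n_epochs=30, seed=0).fit(X[::2], y[::2])
        acc = (som.predict(X[1::2]) == y[1::2]).mean()
        assert acc >= 0.95

    def test_single_class_warns_and_predicts_it(self):
        X, _ = gaussian_classes(seed=2, n=40)
        y = np.array(["only"] * 40)
        with pytest.warns(UserWarning):
            som = rec.SOMClassifier(n_epochs=5, seed=0).fit(X, y)
        assert set(som.predict(X)) == {"only"}

    def test_training_deterministic(self):
        X, y = gaussian_classes(seed=3, n=60)
        s1 = rec.SOMClassifier(n_epochs=10, seed=4).fit(X, y)
        s2 = rec.SOMClassifier(n_epochs=10, seed=4).fit(X, y)
        assert np.array_equal(s1.codebook_, s2.codebook_)
        assert np.array_equal(s1.node_labels_, s2.node_labels_)

    def test_quantisation_error_decreases(self):
        X, y = gaussian_classes(seed=5, n=120)
        som = rec.SOMClassifier(n_epochs=30, seed=0).fit(X, y)
        qe = som.quantisation_errors_
        assert qe[-1] < qe[0]
        # overall trend is downward even if single epochs fluctuate
        assert np.mean(qe[-5:]) <= np.mean(qe[:5])

    def test_codebook_vector_maps_to_node_label(self):
        X, y = gaussian_classes(seed=6, n=80)
        som = rec.SOMClassifier(n_epochs=10, seed=0).fit(X, y)
        node = 37
        raw = som.codebook_[node] * som.scale_ + som.mean_
        assert som.predict(raw[None, :])[0] == som.node_labels_[node]

    def test_grid_is_10_by_10_by_default(self):
        X, y = gaussian_classes(seed=7, n=60)
        som = rec.SOMClassifier(n_epochs=3, seed=0).fit(X, y)
        assert som.codebook_.shape == (100, 9)
        assert len(som.node_labels_) == 100


class TestClassifySegments:
    def _descriptors(self, vectors):
        return [rec.ROIDescriptor(np.asarray(v, float), i, 50 + 10 * i) for i, v in enumerate(vectors)]

    def test_roi_is_largest_hologram_segment(self):
        X, y = gaussian_classes(seed=8, n=100)
        som = rec.SOMClassifier(n_epochs=20, seed=0).fit(X, y)
        holo = X[y == "hologram"][:2]
        bg = X[y == "background"][:1]
        descs = self._descriptors([bg[0], holo[0], holo[1]])
        labels, roi_id = rec.classify_segments(som, descs)
        assert labels[0] == "background"
        assert roi_id == 2  # the larger of the two hologram segments

    def test_background_only_raises(self):
        X, y = gaussian_classes(seed=9, n=100)
        som = rec.SOMClassifier(n_epochs=20, seed=0).fit(X, y)
        bg = X[y == "background"][:3]
        with pytest.raises(rec.NoROIError):
            rec.classify_segments(som, self._descriptors(list(bg)))
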