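"""Camera characterisation: gamma, flat field, polynomial model, selection."""

import numpy as np
import pytest

from holoquant import camera as cam
from holoquant import simulate as sim
from holoquant.color import delta_e_ab, linear_rgb_to_xyz, xyz_to_lab


class TestEstimateGamma:
    def test_exact_recovery_noiseless(self):
        lum = sim.GREY_LUMINANCE
        rgb = lum[:, None] ** (1 / 2.2) * np.ones(3)
        fit = cam.estimate_gamma(rgb, lum)
        assert np.allclose(fit.gamma_rgb, 2.2, atol=1e-9)
        assert fit.fit_residual < 1e-12

    def test_identity_camera_gives_unit_exponents(self):
        lum = sim.GREY_LUMINANCE
        fit = cam.estimate_gamma(lum[:, None] * np.ones(3), lum)
        assert np.allclose(fit.gamma_rgb, 1.0, atol=1e-6)

    def test_exposure_scale_absorbed(self):
        # a constant exposure factor must not bias the exponent
        lum = sim.GREY_LUMINANCE
        rgb = 0.8 * lum[:, None] ** (1 / 1.9) * np.ones(3)
        fit = cam.estimate_gamma(rgb, lum)
        assert np.allclose(fit.gamma_rgb, 1.9, atol=1e-9)
        assert np.allclose(fit.scale_rgb, 0.8, atol=1e-9)

    def test_monte_carlo_recovery_under_noise(self):
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            lum = sim.GREY_LUMINANCE
            rgb = np.clip(lum[:, None] ** (1 / 2.0) + rng.normal(0, 0.005, (6, 3)), 1e-4, 1)
            fit = cam.estimate_gamma(rgb, lum)
            errs.append(np.abs(fit.gamma_rgb - 2.0).max())
        assert np.median(errs) < 0.05

    def test_requires_three_distinct_patches(self):
        with pytest.raises(ValueError):
            cam.estimate_gamma(np.array([[0.5] * 3, [0.5] * 3]), np.array([0.5, 0.5]))


class TestFlatField:
    def test_unit_gain_without_vignette(self, identity_camera):
        ff = cam.fit_flat_field(sim.render_grey_card(identity_camera))
        assert np.allclose(ff.gain_map, 1.0, atol=1e-9)

    def test_corrects_vignetted_card(self):
        cfg = sim.CameraSimConfig(gamma_rgb=(1, 1, 1), vignette_strength=0.3, noise_sd=0.0, seed=0)
        card = sim.render_grey_card(cfg)
        ff = cam.fit_flat_field(card)
        corrected = ff.apply(card)
        assert corrected.max() / corrected.min() < 1.001

    def test_calibration_constants_are_channel_means(self, phone_grey_card):
        ff = cam.fit_flat_field(phone_grey_card)
        assert np.allclose(ff.calibration_constants, phone_grey_card.mean(axis=(0, 1)), atol=1e-9)

    def test_correction_reduces_spatial_variation(self, phone_grey_card):
        ff = cam.fit_flat_field(phone_grey_card)
        corrected = ff.apply(phone_grey_card)
        cv = lambda a: a.std() / a.mean()
        assert cv(corrected[:, :, 1]) < cv(phone_grey_card[:, :, 1])


class TestTermVector:
    def test_all_ones_input(self):
        v = cam.build_term_vector(np.ones(3), "poly20")
        assert np.allclose(v, 1.0)

    def test_direct_powers(self):
        v = cam.build_term_vector(np.array([0.5, 1.0, 1.0]), [(1, 0, 0), (2, 0, 0), (0, 0, 0)])
        assert np.allclose(v, [0.5, 0.25, 1.0])

    def test_term_order_permutes_vector(self):
        rgb = np.array([0.3, 0.6, 0.9])
        terms = [(1, 0, 0), (0, 2, 0), (1, 1, 1)]
        v1 = cam.build_term_vector(rgb, terms)
        v2 = cam.build_term_vector(rgb, terms[::-1])
        assert np.allclose(v1, v2[::-1])

    def test_preset_sizes(self):
        assert {name: len(ts) for name, ts in cam.TERM_PRESETS.items()} == {
            "linear3": 3, "poly5": 5, "poly8": 8, "poly11": 11, "poly20": 20,
        }


class TestPolyModel:
    def test_linear_camera_exactly_invertible(self):
        rng = np.random.default_rng(0)
        mix = np.array([[0.8, 0.15, 0.05], [0.1, 0.85, 0.05], [0.05, 0.1, 0.85]])
        refl = rng.random((24, 3))
        rgb = refl @ mix.T
        xyz = linear_rgb_to_xyz(refl)
        model = cam.fit_poly_model(rgb, xyz, "linear3")
        assert model.median_dE < 1e-6

    def test_richer_basis_never_worse_on_training(self):
        rng = np.random.default_rng(1)
        refl = rng.random((24, 3))
        rgb = np.clip(refl ** 1.1 + 0.02 * refl[:, ::-1], 0, None)  # nonlinear camera
        xyz = linear_rgb_to_xyz(refl)
        m3 = cam.fit_poly_model(rgb, xyz, "linear3")
        m20 = cam.fit_poly_model(rgb, xyz, "poly20")
        assert m20.median_dE <= m3.median_dE

    def test_duplicate_patches_do_not_change_solution(self):
        rng = np.random.default_rng(2)
        refl = rng.random((20, 3))
        xyz = linear_rgb_to_xyz(refl)
        m1 = cam.fit_poly_model(refl, xyz, "poly5")
        m2 = cam.fit_poly_model(np.vstack([refl, refl]), np.vstack([xyz, xyz]), "poly5")
        assert np.allclose(m1.coeffs, m2.coeffs, atol=1e-8)

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError):
            cam.fit_poly_model(np.random.rand(4, 3), np.random.rand(4, 3), "poly20")

    def test_rank_deficient_reported(self):
        rgb = np.tile([[0.5, 0.5, 0.5]], (30, 1))  # a single colour cannot span the basis
        xyz = np.tile([[20.0, 21.0, 22.0]], (30, 1))
        with pytest.raises(np.linalg.LinAlgError):
            cam.fit_poly_model(rgb, xyz, "poly5")


class TestSelectModel:
    def test_single_candidate(self):
        m = cam.fit_poly_model(np.random.rand(10, 3), np.random.rand(10, 3) * 50, "linear3")
        assert cam.select_model([m]) is m

    def test_minimum_median_de_wins(self):
        mk = lambda dE, n: cam.PolyCameraModel(tuple([(1, 0, 0)] * n), np.zeros((3, n)), dE)
        assert cam.select_model([mk(5, 3), mk(2, 8), mk(3, 11)]).median_dE == 2

    def test_tie_breaks_to_fewer_terms(self):
        mk = lambda dE, n: cam.PolyCameraModel(tuple([(1, 0, 0)] * n), np.zeros((3, n)), dE)
        assert cam.select_model([mk(1.5, 11), mk(1.5, 3)]).n_terms == 3

    def test_permutation_invariant(self):
        mk = lambda dE, n: cam.PolyCameraModel(tuple([(1, 0, 0)] * n), np.zeros((3, n)), dE)
        cands = [mk(4, 3), mk(1, 8), mk(2, 11)]
        assert cam.select_model(cands) is cam.select_model(cands[::-1])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cam.select_model([])


class TestEndToEndCharacterisation:
    def test_full_chain_recovers_reference_colours(self, phone_camera, phone_chart, phone_grey_card):
        img, truth = phone_chart
        ch = cam.CameraCharacterizer().fit(
            img, truth.patch_boxes, truth.chart_xyz, truth.grey_indices,
            truth.grey_luminance, phone_grey_card,
        )
        assert np.allclose(ch.gamma_.gamma_rgb, phone_camera.gamma_rgb, rtol=0.03)
        xyz_img = ch.transform(img)
        means = cam.patch_means(xyz_img, truth.patch_boxes)
        dE = delta_e_ab(xyz_to_lab(means), xyz_to_lab(truth.chart_xyz))
        assert np.median(dE) < 2.0

    def test_constant_image_maps_to_constant_xyz(self, phone_chart, phone_grey_card):
        img, truth = phone_chart
        ch = cam.CameraCharacterizer(term_sets=("linear3",)).fit(
            img, truth.patch_boxes, truth.chart_xyz, truth.grey_indices,
            truth.grey_luminance, phone_grey_card,
        )
        const = np.full((512, 512, 3), 0.4)
        out = ch.transform(const)
        # flat field varies per pixel, so compare after removing it
        ch.flat_field_ = None
        out = ch.transform(const)
        assert np.ptp(out.reshape(-1, 3), axis=0).max() < 1e-9

    def test_get_set_params_roundtrip(self):
        ch = cam.CameraCharacterizer()
        ch.set_params(surface_degree=2)
        assert ch.get_params()["surface_degree"] == 2
        with pytest.raises(ValueError):
            ch.set_params(bogus=1)
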