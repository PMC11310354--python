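"""Generator correctness: speckle, deformation model, warping, noise."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import strainkit.synthetic as syn
from strainkit.types import DisplacementField, LoadProtocol


class TestSpeckle:
    def test_seeded_determinism_and_seed_sensitivity(self):
        a = syn.generate_speckle_image(128, 128, seed=1)
        b = syn.generate_speckle_image(128, 128, seed=1)
        c = syn.generate_speckle_image(128, 128, seed=2)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_intensity_range_and_texture(self):
        img = syn.generate_speckle_image(128, 128, seed=1)
        assert img.min() >= 0 and img.max() <= 1
        assert img.std() > 0.01
        # autocorrelation length of the grain: 2-6 px (half-height lag)
        row_band = img[40:50] - img[40:50].mean()
        ac = np.array([
            np.mean(row_band[:, :-lag] * row_band[:, lag:]) for lag in range(1, 12)
        ])
        ac /= np.mean(row_band**2)
        first_below = 1 + int(np.argmax(ac < 0.5))
        assert 2 <= first_below <= 6

    def test_rejects_tiny_images(self):
        with pytest.raises(ValueError):
            syn.generate_speckle_image(16, 128)


class TestTemporalProfile:
    @pytest.mark.parametrize(
        "t, expected",
        [
            (0.0, 0.0),
            (3.0, 1.0),  # end of 3 s ramp
            (8.0, 1.0),  # end of 5 s hold
            (9.5, 0.5),  # halfway down the 3 s relaxation: (11-9.5)/3
            (11.0, 0.0),
            (20.0, 0.0),
        ],
    )
    def test_piecewise_values(self, t, expected):
        assert syn.temporal_profile(t) == pytest.approx(expected)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            syn.temporal_profile(-0.1)


class TestStrainFieldModel:
    def test_zero_strain_gives_zero_field(self, geometry):
        f = syn.build_strain_field(0.0, geometry)
        assert not f.exx.any() and not f.eyy.any() and not f.exy.any()

    def test_superficial_edge_is_75_percent_of_deep(self, geometry):
        f = syn.build_strain_field(0.10, geometry)
        r0, r1 = geometry.depth_extent
        assert f.exx[r0, 0] == pytest.approx(0.075, abs=1e-12)
        assert f.exx[r1, 0] == pytest.approx(0.10, abs=1e-12)

    def test_deep_edge_transverse_strain_from_incompressibility(self, geometry):
        f = syn.build_strain_field(0.10, geometry)
        _, r1 = geometry.depth_extent
        assert f.eyy[r1, 0] == pytest.approx(1 / 1.10 - 1, abs=1e-12)

    def test_out_of_range_strain_rejected(self, geometry):
        with pytest.raises(ValueError):
            syn.build_strain_field(0.5, geometry)

    @settings(max_examples=20, deadline=None)
    @given(eps=st.floats(-0.4, 0.4).filter(lambda e: abs(e) > 1e-3))
    def test_incompressibility_and_ratio_invariants(self, eps):
        geometry = syn.default_geometry((64, 64))
        f = syn.build_strain_field(eps, geometry)
        mask = geometry.tendon_mask
        area = (1 + f.exx) * (1 + f.eyy) - 1
        assert np.abs(area[mask]).max() < 1e-9
        r0, r1 = geometry.depth_extent
        assert f.exx[r0, 0] / f.exx[r1, 0] == pytest.approx(
            geometry.superficial_ratio, abs=1e-9
        )


class TestDisplacement:
    def test_zero_field_zero_displacement(self):
        disp = syn.strain_to_displacement(syn.StrainField.zeros((40, 40)))
        assert not disp.u.any() and not disp.v.any()

    def test_uniform_strain_linear_displacement(self):
        z = np.zeros((40, 40))
        f = syn.StrainField(np.full((40, 40), 0.05), z, z.copy())
        disp = syn.strain_to_displacement(f, anchor=(0, 0))
        x = np.arange(40)
        assert np.allclose(disp.u, np.tile(0.05 * x, (40, 1)), atol=1e-12)

    def test_roundtrip_recovers_prescribed_field(self, geometry):
        truth, disp = syn.make_ground_truth(0.08, geometry)
        rec = syn.strain_of_displacement(disp)
        r0, r1 = geometry.depth_extent
        margin = round(0.1 * 64)
        # away from the kinks of the piecewise depth profile
        kinks = {r0, r1, r0 - margin, r1 + margin}
        rows = [r for r in range(2, 62)
                if all(abs(r - k) > 2 for k in kinks)]
        for comp in ("exx", "exy", "eyy"):
            err = np.abs(getattr(rec, comp) - getattr(truth, comp))
            assert err[rows, :].max() < 1e-3, comp


class TestWarp:
    def test_zero_displacement_is_identity(self, speckle):
        disp = DisplacementField(np.zeros((64, 64)), np.zeros((64, 64)))
        assert np.abs(syn.warp_image(speckle, disp) - speckle).max() < 1e-12

    def test_integer_shift_matches_index_arithmetic(self, speckle):
        disp = DisplacementField(np.full((64, 64), 2.0), np.zeros((64, 64)))
        w = syn.warp_image(speckle, disp)
        assert np.abs(w[:, 2:] - speckle[:, :-2]).max() < 1e-9

    def test_warp_inverse_warp_roundtrip_on_smooth_image(self, speckle,
                                                         geometry):
        from scipy.ndimage import gaussian_filter

        smooth = gaussian_filter(speckle, 3.0)
        truth, disp = syn.make_ground_truth(0.06, geometry)
        back = DisplacementField(-disp.u, -disp.v)
        # forward warp then (approximate) inverse warp
        once = syn.warp_image(smooth, disp)
        again = syn.warp_image(once, back)
        assert np.abs(again[8:-8, 8:-8] - smooth[8:-8, 8:-8]).max() < 1e-2

    def test_shape_mismatch_rejected(self, speckle):
        disp = DisplacementField(np.zeros((32, 32)), np.zeros((32, 32)))
        with pytest.raises(ValueError):
            syn.warp_image(speckle, disp)


class TestNoise:
    def test_zero_strength_is_identity(self, speckle):
        out = syn.add_noise(speckle, syn.NoiseParams.none(), seed=3)
        assert np.array_equal(out, speckle)

    def test_seeded_determinism(self, speckle):
        a = syn.add_noise(speckle, seed=9)
        b = syn.add_noise(speckle, seed=9)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, syn.add_noise(speckle, seed=10))

    def test_additive_sigma_matches_sample_std(self):
        img = np.full((256, 256), 0.5)
        params = syn.NoiseParams(
            speckle_var=(0, 0), additive_sigma=(0.05, 0.05),
            gain=(1, 1), offset=(0, 0),
        )
        out = syn.add_noise(img, params, seed=4)
        assert 0.045 <= (out - img).std() <= 0.055

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            syn.NoiseParams(speckle_var=(-0.1, 0.1))


class TestTrainingSet:
    def test_sample_count_and_determinism(self):
        a = syn.generate_training_set(n_pairs=12, seed=21)
        b = syn.generate_training_set(n_pairs=12, seed=21)
        assert len(a) == 12
        for s, t in zip(a, b):
            assert np.array_equal(s.image_ref, t.image_ref)
            assert np.array_equal(s.image_def, t.image_def)
            assert np.array_equal(s.truth.exx, t.truth.exx)
            assert s.cls == t.cls

    def test_class_counts_within_binomial_bounds(self):
        n = 450
        samples = syn.generate_training_set(n_pairs=n, seed=8)
        counts = {c: 0 for c in ("tension", "compression", "rigid")}
        for s in samples:
            counts[s.cls.label] += 1
        # binomial(450, 1/3): 99% central interval approx 150 +/- 2.58*sd
        sd = np.sqrt(n * (1 / 3) * (2 / 3))
        for c, k in counts.items():
            assert abs(k - n / 3) < 2.58 * sd + 1, counts

    def test_class_sign_consistency(self, geometry):
        samples = syn.generate_training_set(n_pairs=30, seed=13)
        mask = geometry.tendon_mask
        for s in samples:
            med = np.median(s.truth.exx[mask])
            if s.cls.label == "tension":
                assert med > 0
            elif s.cls.label == "compression":
                assert med < 0
            else:
                assert med == 0

    def test_ground_truth_invariants_hold_for_generated_samples(self, geometry):
        samples = syn.generate_training_set(n_pairs=10, seed=17)
        mask = geometry.tendon_mask
        r0, r1 = geometry.depth_extent
        for s in samples:
            area = (1 + s.truth.exx) * (1 + s.truth.eyy) - 1
            assert np.abs(area[mask]).max() < 1e-9
            if s.cls.label != "rigid":
                ratio = s.truth.exx[r0, 0] / s.truth.exx[r1, 0]
                assert ratio == pytest.approx(0.75, abs=1e-9)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_training_set(n_pairs=2)
        with pytest.raises(ValueError):
            syn.generate_training_set(n_pairs=10, class_mix=(0.5, 0.5, 0.5))


class TestTestCases:
    def test_default_levels_and_peaks(self, benchmark_reduced_noise, geometry):
        cases = benchmark_reduced_noise
        assert [c.eps_long_max for c in cases] == [0.04, 0.07, 0.10, 0.13, 0.16]
        _, r1 = geometry.depth_extent
        for case in cases:
            peak = max(t.exx[r1, 0] for t in case.truths)
            assert peak == pytest.approx(case.eps_long_max, abs=1e-9)

    def test_profile_returns_to_zero(self, benchmark_reduced_noise):
        case = benchmark_reduced_noise[2]
        assert np.abs(case.truths[-1].exx).max() < 1e-12

    def test_level_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_test_cases(levels=(0.6,))
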