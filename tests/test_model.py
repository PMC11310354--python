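"""Architecture contracts: shapes, determinism, parameter arithmetic."""

import numpy as np
import pytest

from strainkit import model as M
from strainkit.types import TENSION, DeformationClass

RNG = np.random.default_rng(7)


class TestClassifier:
    def test_same_seed_identical_parameters(self):
        a = M.build_classifier((16, 16), (4, 8), fc_width=16, seed=3)
        b = M.build_classifier((16, 16), (4, 8), fc_width=16, seed=3)
        for pa, pb in zip(a.params(), b.params()):
            assert np.array_equal(pa.value, pb.value)

    def test_probabilities_form_simplex(self):
        clf = M.build_classifier((16, 16), (4, 8), fc_width=16, seed=3)
        x = RNG.normal(size=(5, 16, 16, 2))
        probs = clf.predict_probs(x)
        assert probs.shape == (5, 3)
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_parameter_count_matches_hand_tally(self):
        # conv(2->4)+BN: 76+8; conv(4->8)+BN: 296+16;
        # flatten 4*4*8=128 -> fc16: 2064; fc16 -> 3: 51
        clf = M.build_classifier((16, 16), (4, 8), fc_width=16, seed=0)
        assert M.param_count(clf) == 76 + 8 + 296 + 16 + 2064 + 51

    def test_undersized_input_rejected(self):
        with pytest.raises(ValueError):
            M.build_classifier((8, 8), (4, 8, 16, 32))


class TestRegressor:
    def test_output_shape_matches_input_with_three_channels(self):
        net = M.build_regressor((3, 4), seed=1, features="raw")
        out = net.predict_field(RNG.normal(size=(2, 16, 16, 2)))
        assert out.shape == (2, 16, 16, 3)
        assert np.all(np.isfinite(out))

    def test_parameter_count_and_skip_contribution(self):
        # with skips: enc0 153 + bottleneck 276 + dec0 288 + head 84 = 801;
        # without skips the decoder conv loses 3x3*3(skip)*3 = 81 weights
        with_sk = M.build_regressor((3, 4), use_skips=True, seed=0, features="raw")
        without = M.build_regressor((3, 4), use_skips=False, seed=0, features="raw")
        assert M.param_count(with_sk) == 801
        assert M.param_count(with_sk) - M.param_count(without) == 81

    def test_same_seed_same_outputs(self):
        x = RNG.normal(size=(1, 16, 16, 2))
        a = M.build_regressor((3, 4), seed=9, features="raw").predict_field(x)
        b = M.build_regressor((3, 4), seed=9, features="raw").predict_field(x)
        assert np.array_equal(a, b)

    def test_indivisible_input_rejected(self):
        net = M.build_regressor((3, 4, 5), seed=0, features="raw")
        with pytest.raises(ValueError):
            net.predict_field(RNG.normal(size=(1, 18, 18, 2)))

    def test_translation_covariance_on_interior(self):
        """Shifting the input by a pool-aligned offset shifts the output
        identically, away from the zero-padded borders."""
        net = M.build_regressor((4, 8), seed=2, features="raw")  # pool factor 2
        base = RNG.normal(size=(1, 32, 64, 2))
        shift = 8
        rolled = np.roll(base, shift, axis=2)
        out_a = net.predict_field(base)[0]
        out_b = net.predict_field(rolled)[0]
        # crop beyond the network's receptive field from every border
        inner = np.abs(
            np.roll(out_a, shift, axis=1)[14:-14, 24:-24]
            - out_b[14:-14, 24:-24]
        )
        assert inner.max() < 1e-10


class TestCorrespondenceFeatures:
    def test_channel_count_matches_declaration(self, speckle):
        feats = M.correspondence_features(speckle, speckle)
        assert feats.shape == speckle.shape + (
            M.FEATURE_CHANNELS["correspondence"],
        )
        assert np.all(np.isfinite(feats))

    def test_identical_frames_give_zero_displacement_estimates(self, speckle):
        feats = M.correspondence_features(speckle, speckle)
        # Lucas-Kanade channels (15, 16) and their gradients (17, 18) are
        # exactly zero when the frames coincide; the soft-argmin maps are
        # only approximately zero (texture asymmetry)
        assert not feats[..., 15:19].any()
        assert np.abs(np.median(feats[..., 13])) < 0.5

    def test_translation_shifts_cost_volume_minimum(self, speckle):
        import strainkit.synthetic as syn
        from strainkit.types import DisplacementField

        disp = DisplacementField(np.full((64, 64), 3.0), np.zeros((64, 64)))
        moved = syn.warp_image(speckle, disp)
        feats = M.correspondence_features(speckle, moved)
        cost = feats[8:-8, 8:-8, 2:2 + len(M.COST_SHIFTS_X)]
        best = np.array(M.COST_SHIFTS_X)[np.argmin(
            cost.reshape(-1, cost.shape[-1]), axis=1
        )]
        assert np.median(best) == 3

    def test_deterministic(self, speckle):
        a = M.correspondence_features(speckle, np.clip(speckle + 0.01, 0, 1))
        b = M.correspondence_features(speckle, np.clip(speckle + 0.01, 0, 1))
        assert np.array_equal(a, b)


class TestClassifyPair:
    def test_returns_deterministic_class(self, speckle):
        clf = M.build_classifier((64, 64), (4, 8), fc_width=8, seed=5)
        from strainkit.training import TwoStageModel  # noqa: F401  (layout)

        other = np.clip(speckle + 0.01, 0, 1)
        c1 = M.classify_pair(clf, speckle, other)
        c2 = M.classify_pair(clf, speckle, other)
        assert isinstance(c1, DeformationClass)
        assert c1 == c2

    def test_tie_breaks_to_lowest_index(self):
        assert DeformationClass.from_index(
            int(np.argmax([0.4, 0.4, 0.2]))
        ) == TENSION

    def test_non_finite_input_rejected(self, speckle):
        clf = M.build_classifier((64, 64), (4, 8), fc_width=8, seed=5)
        bad = speckle.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            M.classify_pair(clf, speckle, bad)


class TestCheckpoints:
    def test_roundtrip_preserves_outputs(self, tmp_path):
        net = M.build_regressor((3, 4), seed=4, features="raw")
        x = RNG.normal(size=(1, 8, 8, 2))
        before = net.predict_field(x)
        path = tmp_path / "reg.npz"
        M.save_checkpoint(net, path)
        after = M.load_checkpoint(path).predict_field(x)
        assert np.array_equal(before, after)

    def test_classifier_roundtrip(self, tmp_path):
        clf = M.build_classifier((16, 16), (4, 8), fc_width=16, seed=4)
        x = RNG.normal(size=(2, 16, 16, 2))
        path = tmp_path / "clf.npz"
        M.save_checkpoint(clf, path)
        assert np.array_equal(
            clf.predict_probs(x), M.load_checkpoint(path).predict_probs(x)
        )

    def test_corrupted_file_raises_format_error(self, tmp_path):
        path = tmp_path / "bad.npz"
        np.savez(path, junk=np.zeros(3))
        with pytest.raises(ValueError, match="checkpoint"):
            M.load_checkpoint(path)
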