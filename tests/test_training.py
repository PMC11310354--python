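"""Loss definitions, splitting, and the optimization loop."""

import numpy as np
import pytest

import strainkit.synthetic as syn
from strainkit.training import (
    TrainingConfig,
    cross_entropy,
    mean_l2_loss,
    split_dataset,
    train_all,
)
from strainkit.types import DeformationClass, StrainField, SyntheticSample

RNG = np.random.default_rng(3)


def brute_force_cross_entropy(probs, label_index):
    total = 0.0
    for i, p in enumerate(probs):
        y = 1.0 if i == label_index else 0.0
        total -= y * np.log(max(min(p, 1.0), 1e-12))
    return total


def brute_force_mean_l2(pred, truth):
    """Scalar-loop evaluation of the tensor double-sum loss."""
    n = len(pred)
    total = 0.0
    for p_f, t_f in zip(pred, truth):
        h, w = p_f.shape
        for r in range(h):
            for c in range(w):
                dp = p_f.tensor()[r, c] - t_f.tensor()[r, c]
                for i in range(2):
                    for j in range(2):
                        total += abs(dp[i, j]) ** 2
    return total / (n * h * w)


class TestCrossEntropy:
    @pytest.mark.parametrize(
        "probs, label, expected",
        [
            ((1.0, 0.0, 0.0), 0, 0.0),
            ((1 / 3, 1 / 3, 1 / 3), 1, np.log(3)),
            ((0.5, 0.25, 0.25), 0, np.log(2)),
        ],
    )
    def test_closed_form_values(self, probs, label, expected):
        assert cross_entropy(probs, label) == pytest.approx(expected, abs=1e-12)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy((0.5, 0.5), 0)

    def test_matches_brute_force_on_random_inputs(self):
        for _ in range(50):
            p = RNG.dirichlet(np.ones(3))
            k = int(RNG.integers(3))
            assert cross_entropy(p, k) == pytest.approx(
                brute_force_cross_entropy(p, k), abs=1e-10
            )


class TestMeanL2:
    def _field(self, arr3):
        return StrainField(arr3[0], arr3[1], arr3[2])

    def test_identical_fields_give_zero(self):
        f = self._field(RNG.normal(size=(3, 4, 4)))
        assert mean_l2_loss([f], [f]) == 0.0

    def test_single_pixel_normal_component(self):
        p = self._field(np.array([[[0.1]], [[0.0]], [[0.0]]]))
        t = self._field(np.zeros((3, 1, 1)))
        assert mean_l2_loss([p], [t]) == pytest.approx(0.01, abs=1e-15)

    def test_single_pixel_shear_counts_twice(self):
        p = self._field(np.array([[[0.0]], [[0.1]], [[0.0]]]))
        t = self._field(np.zeros((3, 1, 1)))
        assert mean_l2_loss([p], [t]) == pytest.approx(0.02, abs=1e-15)

    def test_matches_brute_force_tensor_loops(self):
        preds = [self._field(RNG.normal(size=(3, 3, 5))) for _ in range(3)]
        truths = [self._field(RNG.normal(size=(3, 3, 5))) for _ in range(3)]
        assert mean_l2_loss(preds, truths) == pytest.approx(
            brute_force_mean_l2(preds, truths), abs=1e-10
        )

    def test_shape_mismatch_rejected(self):
        a = self._field(np.zeros((3, 2, 2)))
        b = self._field(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError):
            mean_l2_loss([a], [b])


def _fake_samples(n, mix=(1 / 3, 1 / 3, 1 / 3), seed=0):
    rng = np.random.default_rng(seed)
    labels = rng.choice(3, size=n, p=mix)
    z = np.zeros((2, 2))
    return [
        SyntheticSample(z, z, StrainField.zeros((2, 2)),
                        DeformationClass.from_index(int(k)), seed=i)
        for i, k in enumerate(labels)
    ]


class TestSplit:
    def test_headline_sizes(self):
        train, val = split_dataset(_fake_samples(3750), 0.2, seed=1)
        assert len(train) == 3000 and len(val) == 750

    def test_deterministic_and_disjoint(self):
        samples = _fake_samples(100, seed=5)
        t1, v1 = split_dataset(samples, 0.2, seed=2)
        t2, v2 = split_dataset(samples, 0.2, seed=2)
        assert [s.seed for s in t1] == [s.seed for s in t2]
        ids_t = {id(s) for s in t1}
        ids_v = {id(s) for s in v1}
        assert not ids_t & ids_v
        assert len(ids_t | ids_v) == 100

    def test_stratification_keeps_all_classes_in_both_splits(self):
        samples = _fake_samples(30, mix=(0.8, 0.1, 0.1), seed=3)
        train, val = split_dataset(samples, 0.2, seed=0)
        assert {s.cls.label for s in train} == {s.cls.label for s in val} == {
            "tension", "compression", "rigid"
        }

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(_fake_samples(10), 1.5)


class TestTrainAll:
    @pytest.fixture(scope="class")
    def micro_run(self):
        """A very small but complete training run (noise-free data)."""
        dataset = syn.generate_training_set(
            n_pairs=45, noise_ranges=syn.NoiseParams.none(), seed=31,
            image_shape=(32, 32),
        )
        config = TrainingConfig(
            epochs=6, batch_classifier=16, batch_regressor=4, seed=31,
            classifier_widths=(4, 8), regressor_widths=(4, 8, 16),
            fc_width=16, profile="tiny",
        )
        return train_all(dataset, config)

    def test_training_loss_improves_by_best_epoch(self, micro_run):
        _, report = micro_run
        for name, hist in report.history.items():
            best = report.best_epoch[name]
            assert hist["train_loss"][best] < hist["train_loss"][0] or best == 0

    def test_report_metrics_well_formed(self, micro_run):
        models, report = micro_run
        assert 0.0 <= report.final_val_accuracy <= 1.0
        assert set(models.regressors) == {"tension", "compression", "rigid"}
        for v in report.final_val_l2.values():
            assert np.isfinite(v) and v >= 0

    def test_rigid_regressor_learns_zero_field_regime(self, micro_run):
        # the rigid class has identically zero truth: an easy regime the
        # network must essentially solve even at micro scale
        _, report = micro_run
        assert report.final_val_l2["rigid"] < 1e-3

    def test_seeded_rerun_reproduces_metrics(self, micro_run):
        dataset = syn.generate_training_set(
            n_pairs=45, noise_ranges=syn.NoiseParams.none(), seed=31,
            image_shape=(32, 32),
        )
        config = TrainingConfig(
            epochs=6, batch_classifier=16, batch_regressor=4, seed=31,
            classifier_widths=(4, 8), regressor_widths=(4, 8, 16),
            fc_width=16, profile="tiny",
        )
        _, report2 = train_all(dataset, config)
        _, report1 = micro_run
        assert report1.final_val_accuracy == report2.final_val_accuracy
        for k in report1.final_val_l2:
            assert report1.final_val_l2[k] == pytest.approx(
                report2.final_val_l2[k], abs=1e-6
            )

    def test_missing_class_rejected(self):
        dataset = syn.generate_training_set(
            n_pairs=12, class_mix=(1.0, 0.0, 0.0), seed=1,
            image_shape=(32, 32),
        )
        with pytest.raises(ValueError, match="missing classes"):
            train_all(dataset, TrainingConfig(epochs=1, seed=0))
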