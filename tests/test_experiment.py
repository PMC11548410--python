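"""Fold protocol, augmentation arithmetic and metric identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinegan import (
    AugmentationRatio,
    SpectralCGAN,
    augment_training_set,
    compute_metrics,
    run_experiment,
    stratified_folds,
    synth_count,
)
from kinegan.experiment import DEFAULT_RATIOS, _largest_remainder
from kinegan.simulate import simulate_dataset

from conftest import SMALL_TRIAL_GAN_PARAMS


class TestStratifiedFolds:
    def test_exact_counts_under_divisibility(self):
        labels = np.repeat(np.arange(10), 10)
        folds = stratified_folds(labels, k=5, seed=0)
        for fold in folds:
            assert len(fold) == 20
            counts = np.bincount(labels[fold], minlength=10)
            assert np.all(counts == 2)

    def test_partition_contract(self):
        labels = np.random.default_rng(0).integers(0, 7, size=83)
        folds = stratified_folds(labels, k=5, seed=1)
        combined = np.concatenate(folds)
        assert len(combined) == 83
        assert len(np.unique(combined)) == 83

    def test_stratification_within_one(self):
        labels = np.random.default_rng(1).integers(0, 4, size=101)
        folds = stratified_folds(labels, k=5, seed=2)
        for cls in range(4):
            per_fold = [np.sum(labels[f] == cls) for f in folds]
            assert max(per_fold) - min(per_fold) <= 1

    def test_deterministic_given_seed(self):
        labels = np.random.default_rng(2).integers(0, 5, size=60)
        a = stratified_folds(labels, k=5, seed=9)
        b = stratified_folds(labels, k=5, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_small_classes_still_dealt(self):
        labels = np.array([0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 1])  # class 1 has < k members
        folds = stratified_folds(labels, k=5, seed=0)
        assert sum(len(f) for f in folds) == 12

    def test_empty_labels_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds(np.array([]), k=5)


class TestSynthCount:
    @pytest.mark.parametrize(
        "n,ratio,expected",
        [
            (100, AugmentationRatio(1, 1), 100),
            (100, AugmentationRatio(2, 3), 150),
            (100, AugmentationRatio(1, 0), 0),
            (100, AugmentationRatio(2, 1), 50),
            (100, AugmentationRatio(1, 2), 200),
        ],
    )
    def test_counts(self, n, ratio, expected):
        assert synth_count(n, ratio) == expected

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            AugmentationRatio(0, 1)

    def test_display_names(self):
        assert [r.name for r in DEFAULT_RATIOS] == ["Real Only", "2:1", "1:1", "2:3", "1:2"]
        assert AugmentationRatio.parse("real").name == "Real Only"
        assert AugmentationRatio.parse("2:3") == AugmentationRatio(2, 3)


@pytest.fixture(scope="module")
def tiny_gan():
    ds = simulate_dataset(2, seed=0)
    gan = SpectralCGAN(random_state=0, epochs=1, **SMALL_TRIAL_GAN_PARAMS)
    return gan.fit(ds.signals(), ds.labels), ds


class TestAugmentation:

    def test_real_only_is_identity(self, tiny_gan):
        gan, ds = tiny_gan
        assert augment_training_set(ds, gan, AugmentationRatio(1, 0)) is ds

    def test_one_to_two_allocation_per_class(self, tiny_gan):
        gan, ds = tiny_gan
        subset = ds.subset(np.flatnonzero(np.isin(ds.labels, [0, 1, 2])))  # 3 classes x 2
        out = augment_training_set(subset, gan, AugmentationRatio(1, 2), rng=0)
        assert len(out) == 18
        synth = out.subset(out.provenance == "synthetic")
        assert np.all(np.bincount(synth.labels, minlength=3)[:3] == 4)

    def test_conservation_for_every_ratio(self, tiny_gan):
        gan, ds = tiny_gan
        for ratio in DEFAULT_RATIOS:
            out = augment_training_set(ds, gan, ratio, rng=1)
            assert len(out) == len(ds) + synth_count(len(ds), ratio)

    def test_largest_remainder_sums(self):
        quotas = np.array([3.4, 2.3, 1.3])
        assert _largest_remainder(quotas, 7).sum() == 7
        assert np.array_equal(_largest_remainder(quotas, 7), [4, 2, 1])


class TestComputeMetrics:
    def test_perfect_matrix(self):
        m = compute_metrics(np.diag([5, 3, 7]))
        assert (m["precision"], m["recall"], m["f1"], m["accuracy"]) == (1.0, 1.0, 1.0, 1.0)

    def test_two_class_hand_computation(self):
        m = compute_metrics(np.array([[8, 2], [3, 7]]))
        assert m["accuracy"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(0.75)
        assert m["precision"] == pytest.approx((10 * 8 / 11 + 10 * 7 / 9) / 20)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_weighted_recall_equals_accuracy(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 8))
        conf = rng.integers(0, 30, size=(k, k))
        if conf.sum() == 0:
            conf[0, 0] = 1
        m = compute_metrics(conf)
        assert m["recall"] == pytest.approx(m["accuracy"], abs=1e-12)

    def test_zero_prediction_flagged(self):
        m = compute_metrics(np.array([[5, 0], [3, 0]]))
        assert m["zero_predicted"] == [1]

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.zeros((3, 3), dtype=int))


@pytest.fixture(scope="module")
def smoke_report():
    ds = simulate_dataset(3, seed=10)
    gan_params = {**SMALL_TRIAL_GAN_PARAMS, "epochs": 1}
    fcn_params = {"conv1_filters": 8, "conv2_filters": 8, "dense_units": 16,
                  "epochs": 1, "batch_size": 64}
    return run_experiment(
        ds, ratios=DEFAULT_RATIOS, k=5, seed=0,
        gan_params=gan_params, fcn_params=fcn_params,
    )


class TestRunExperiment:

    def test_report_has_table_shape(self, smoke_report):
        summary = smoke_report.summary()
        assert list(summary["condition"]) == ["Real Only", "2:1", "1:1", "2:3", "1:2"]
        for name in ("precision", "recall", "f1", "accuracy"):
            assert name in summary.columns and f"{name}_sd" in summary.columns
            assert summary[name].between(0, 1).all()

    def test_recall_column_equals_accuracy_column(self, smoke_report):
        summary = smoke_report.summary()
        assert np.allclose(summary["recall"], summary["accuracy"], atol=1e-12)

    def test_fold_log_counts(self, smoke_report):
        log = smoke_report.provenance_log
        assert len(log) == 25  # 5 folds x 5 conditions
        for entry in log:
            if entry["condition"] == "1:1":
                assert entry["n_synth"] == entry["n_real_train"]
            if entry["condition"] == "Real Only":
                assert entry["n_synth"] == 0

    def test_synthetic_input_rejected(self):
        ds = simulate_dataset(1, seed=0, provenance="synthetic")
        with pytest.raises(ValueError):
            run_experiment(ds)
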