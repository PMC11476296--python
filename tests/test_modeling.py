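import numpy as np
import pytest
from sklearn.dummy import DummyClassifier

from protamine_ml import (
    MODEL_REGISTRY,
    GANConfig,
    ModelSpec,
    SimulationConfig,
    SmoteConfig,
    SplitSpec,
    cross_validate,
    predict,
    run_experiment,
    simulate_dataset,
    split_dataset,
    train_model,
)
from protamine_ml.modeling import report_to_frame


class TestSplitDataset:
    def test_balanced_100_gives_stratified_80_20(self, benchmark_dataset):
        subset = benchmark_dataset.subset(
            np.r_[np.arange(50), np.arange(200, 250)]
        )
        train, test = split_dataset(subset, SplitSpec(seed=0))
        assert len(train) == 80 and len(test) == 20
        assert train.class_counts() == {0: 40, 1: 40}
        assert test.class_counts() == {0: 10, 1: 10}

    def test_partition_and_determinism(self, benchmark_dataset):
        spec = SplitSpec(seed=5)
        train, test = split_dataset(benchmark_dataset, spec)
        again_train, again_test = split_dataset(benchmark_dataset, spec)
        assert sorted(train.ids + test.ids) == sorted(benchmark_dataset.ids)
        assert set(train.ids).isdisjoint(test.ids)
        assert train.ids == again_train.ids and test.ids == again_test.ids

    def test_rounding_ties_go_to_train(self, benchmark_dataset):
        subset = benchmark_dataset.subset(np.arange(0, 400, 13))  # n = 31
        train, test = split_dataset(
            subset, SplitSpec(stratified=False, seed=1)
        )
        assert len(train) == 25  # ceil(0.8 * 31)
        assert len(test) == 6

    def test_too_small_input_rejected(self, benchmark_dataset):
        with pytest.raises(ValueError):
            split_dataset(benchmark_dataset.subset(np.arange(5)), SplitSpec())


class TestCrossValidate:
    def test_mlp_on_separable_benchmark(self, benchmark_dataset):
        report = cross_validate(
            benchmark_dataset, ModelSpec("MLP", seed=0), folds=10, seed=0
        )
        assert report.summary["acc"] >= 0.95
        assert len(report.folds) == 10

    def test_constant_model_scores_majority_fraction(self, benchmark_dataset):
        MODEL_REGISTRY["DUMMY"] = lambda seed, kw: DummyClassifier(
            strategy="most_frequent"
        )
        try:
            subset = benchmark_dataset.subset(
                np.r_[np.arange(40), np.arange(200, 260)]
            )  # 40 pos, 60 neg
            report = cross_validate(subset, ModelSpec("DUMMY"), folds=10, seed=0)
            assert report.summary["acc"] == pytest.approx(0.6, abs=1e-9)
        finally:
            MODEL_REGISTRY.pop("DUMMY")

    def test_folds_partition_training_set(self, benchmark_dataset):
        from protamine_ml.modeling import make_folds

        pairs = make_folds(benchmark_dataset, n_folds=10, seed=3)
        sizes = [len(val) for _, val in pairs]
        assert max(sizes) - min(sizes) <= 1
        all_ids = sorted(i for _, val in pairs for i in val.ids)
        assert all_ids == sorted(benchmark_dataset.ids)

    def test_too_few_rows_per_class_rejected(self, benchmark_dataset):
        tiny = benchmark_dataset.subset(np.r_[np.arange(5), np.arange(200, 205)])
        with pytest.raises(ValueError):
            cross_validate(tiny, ModelSpec("KNN"), folds=10)


class TestTrainPredict:
    def test_fit_on_separable_benchmark_and_refit_determinism(
        self, benchmark_dataset
    ):
        spec = ModelSpec("RF", seed=7)
        model = train_model(benchmark_dataset, spec)
        scores = model.scores(benchmark_dataset.features)
        acc = np.mean((scores >= 0.5).astype(int) == benchmark_dataset.labels)
        assert acc >= 0.99
        again = train_model(benchmark_dataset, spec)
        np.testing.assert_array_equal(
            scores, again.scores(benchmark_dataset.features)
        )

    def test_prediction_labels_follow_threshold(self, benchmark_dataset):
        model = train_model(benchmark_dataset, ModelSpec("LR", seed=0))
        results = predict(model, benchmark_dataset.features[:20])
        for result in results:
            assert result.label == ("YES" if result.score >= 0.5 else "NO")
            assert 0.0 <= result.score <= 1.0

    def test_threshold_sweep_changes_labels_monotonically(self, benchmark_dataset):
        model = train_model(benchmark_dataset, ModelSpec("LR", seed=0))
        scores = model.scores(benchmark_dataset.features)
        yes_counts = [
            int(np.sum(scores >= t)) for t in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert yes_counts == sorted(yes_counts, reverse=True)

    def test_wrong_feature_width_rejected(self, benchmark_dataset):
        model = train_model(benchmark_dataset, ModelSpec("NB"))
        with pytest.raises(ValueError):
            model.scores(np.zeros((3, 7)))

    def test_nan_features_rejected(self, benchmark_dataset):
        model = train_model(benchmark_dataset, ModelSpec("NB"))
        bad = np.full((1, benchmark_dataset.n_features), np.nan)
        with pytest.raises(ValueError):
            model.scores(bad)

    def test_single_class_training_rejected(self, benchmark_dataset):
        positives = benchmark_dataset.subset(
            np.where(benchmark_dataset.labels == 1)[0]
        )
        with pytest.raises(ValueError):
            train_model(positives, ModelSpec("LR"))


@pytest.fixture(scope="module")
def small_report(benchmark_records):
    return run_experiment(
        benchmark_records[:60] + benchmark_records[200:300],  # 60 pos, 100 neg
        augmentations=("none", "smote", "gan"),
        model_specs=[ModelSpec("LR"), ModelSpec("NB"), ModelSpec("KNN")],
        split_spec=SplitSpec(seed=0, leakage_mode="leaky"),
        smote_config=SmoteConfig(seed=0),
        gan_config=GANConfig(epochs=15, seed=0),
        cv_folds=5,
    )


class TestRunExperiment:
    def test_report_shape_and_labelling(self, small_report):
        assert small_report["config"]["leakage_mode"] == "leaky"
        assert set(small_report["results"]) == {"none", "smote", "gan"}
        for block in small_report["results"].values():
            assert set(block) == {"LR", "NB", "KNN"}
            for entry in block.values():
                assert set(entry) == {"cv", "cv_folds", "test"}
                assert len(entry["cv_folds"]) == 5

    def test_metrics_within_ranges(self, small_report):
        for block in small_report["results"].values():
            for entry in block.values():
                for phase in ("cv", "test"):
                    values = entry[phase]
                    for key in ("acc", "recall", "precision", "f1", "fpr", "auc"):
                        assert 0.0 <= values[key] <= 1.0
                    for key in ("kappa", "mcc"):
                        assert -1.0 <= values[key] <= 1.0

    def test_flat_csv_export(self, small_report):
        frame = report_to_frame(small_report)
        assert len(frame) == 3 * 3 * 2  # augmentations x algorithms x phases
        assert {"leakage_mode", "augmentation", "algorithm", "phase", "acc"} <= set(
            frame.columns
        )

    def test_leakage_inflates_metrics_on_average(self):
        """Augment-then-split (leaky mode) leaks synthetic neighbours of test
        points into training; across seeds its test metrics should not fall
        below the leakage-safe protocol's."""
        leaky_acc, safe_acc = [], []
        for seed in range(10):
            records = simulate_dataset(
                SimulationConfig(
                    n_pos=40, n_neg=120, pos_arg_fraction=0.08, seed=100 + seed
                )
            )
            for mode, bucket in (("leaky", leaky_acc), ("safe", safe_acc)):
                report = run_experiment(
                    records,
                    augmentations=("smote",),
                    model_specs=[ModelSpec("KNN")],
                    split_spec=SplitSpec(seed=seed, leakage_mode=mode),
                    smote_config=SmoteConfig(seed=seed),
                    cv_folds=5,
                )
                bucket.append(
                    report["results"]["smote"]["KNN"]["test"]["acc"]
                )
        assert np.mean(leaky_acc) >= np.mean(safe_acc) - 1e-9
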