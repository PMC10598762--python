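import math

import numpy as np
import pytest
import scipy.sparse as sp

from barcodeid.barcode_io import BarcodeRecord
from barcodeid.classify import (
    ALGORITHMS,
    CVPlan,
    GBDTConfig,
    ModelBundle,
    cross_validate_estimator,
    make_classifier,
    predict_species,
    predictions_frame,
    split_train_test,
    sweep,
    train_baseline,
    train_best_classifier,
)
from barcodeid.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="module")
def tuned_bundle(separable_dataset):
    """One small tuned model shared by the training-contract tests."""
    return train_best_classifier(
        separable_dataset, k=5, init_points=2, n_iter=2, seed=13,
        early_stopping_rounds=None,
    )


class TestGBDTConfig:
    def test_defaults_are_inside_declared_ranges(self):
        GBDTConfig()  # must not raise

    @pytest.mark.parametrize("kwargs", [
        {"max_depth": 11}, {"gamma": 1.5}, {"learning_rate": 0.0},
        {"n_estimators": 50},
    ])
    def test_out_of_range_values_rejected(self, kwargs):
        with pytest.raises(ValueError, match="range"):
            GBDTConfig(**kwargs)


class TestSplit:
    def test_stratified_counts_ten_per_class(self, separable_dataset):
        train, test = split_train_test(separable_dataset, test_fraction=0.2, seed=0)
        assert all(n == 2 for n in test.species_counts().values())
        assert all(n == 8 for n in train.species_counts().values())

    def test_split_is_a_partition(self, separable_dataset):
        train, test = split_train_test(separable_dataset, test_fraction=0.2, seed=1)
        train_ids = {r.record_id for r in train.records}
        test_ids = {r.record_id for r in test.records}
        assert train_ids.isdisjoint(test_ids)
        assert train_ids | test_ids == {r.record_id for r in separable_dataset.records}

    def test_same_seed_gives_identical_partition(self, separable_dataset):
        first = split_train_test(separable_dataset, seed=5)
        second = split_train_test(separable_dataset, seed=5)
        assert [r.record_id for r in first[0].records] == [
            r.record_id for r in second[0].records
        ]

    def test_singleton_class_is_hard_error(self):
        config = SyntheticConfig(n_species=2, counts=[5, 1],
                                 length_range=(50, 60), seed=0)
        dataset, _ = generate_dataset(config)
        with pytest.raises(ValueError, match="min_count"):
            split_train_test(dataset)


class TestCVPlan:
    def test_folds_partition_and_stratify_within_one(self, separable_dataset):
        y = np.asarray(separable_dataset.labels)
        plan = CVPlan()
        seen = []
        for _, test_idx in plan.splitter().split(np.zeros((y.size, 1)), y):
            seen.extend(test_idx)
            _, fold_counts = np.unique(y[test_idx], return_counts=True)
            # 40 records / 5 folds / 4 classes = 2 per class per fold
            assert np.all(np.abs(fold_counts - 2) <= 1)
        assert sorted(seen) == list(range(y.size))


class TestBaselines:
    def test_all_algorithms_accept_the_same_count_matrix(self):
        X = sp.csr_matrix(np.array([[3, 0, 1], [0, 2, 2], [1, 1, 0], [4, 0, 0]]))
        y = np.array([0, 1, 1, 0])
        for algorithm in ALGORITHMS:
            estimator = make_classifier(algorithm, seed=0)
            estimator.fit(X, y)
            proba = estimator.predict_proba(X)
            assert proba.shape == (4, 2)

    def test_multinomial_nb_matches_hand_computed_posterior(self):
        # 2 classes, 2 tokens; Laplace-smoothed multinomial likelihoods
        X = sp.csr_matrix(np.array([[4, 0], [3, 1], [0, 4], [1, 3]]))
        y = np.array([0, 0, 1, 1])
        nb = make_classifier("naive_bayes")
        nb.fit(X, y)
        # class 0: token counts (7,1)+1 smoothing over 8+2 -> theta0=(0.8,0.2)
        # class 1: theta1=(0.2,0.8); priors equal
        query = np.array([[2, 1]])
        like0 = 0.8**2 * 0.2
        like1 = 0.2**2 * 0.8
        expected = like0 / (like0 + like1)
        proba = nb.predict_proba(sp.csr_matrix(query))
        assert proba[0, 0] == pytest.approx(expected)
        assert nb.predict(sp.csr_matrix(query))[0] == 0

    def test_forest_and_boosting_solve_noiseless_two_species(self):
        config = SyntheticConfig(n_species=2, counts=[8, 8], length_range=(60, 100),
                                 divergence=0.2, noise=0.0, seed=21)
        dataset, _ = generate_dataset(config)
        for algorithm in ("random_forest", "gbdt"):
            bundle = train_baseline(dataset, algorithm, k=4, seed=0)
            predictions = predict_species(bundle, dataset.records)
            assert all(
                p.species == r.species
                for p, r in zip(predictions, dataset.records)
            )

    def test_unknown_algorithm_is_usage_error(self, separable_dataset):
        with pytest.raises(ValueError, match="unknown algorithm"):
            train_baseline(separable_dataset, "svm")


class TestTrainBestClassifier:
    def test_tuned_parameters_inside_declared_ranges(self, tuned_bundle):
        config = tuned_bundle.config
        assert 5 <= config.max_depth <= 10
        assert 0.0 <= config.gamma <= 1.0
        assert 0.0 < config.learning_rate <= 1.0
        assert 100 <= config.n_estimators <= 400
        for evaluation in tuned_bundle.search_history:
            assert 5 <= evaluation.params["max_depth"] <= 10
            assert 100 <= evaluation.params["n_estimators"] <= 400

    def test_cv_reports_cover_all_folds_with_valid_scores(self, tuned_bundle):
        assert len(tuned_bundle.cv_reports) == 5
        for report in tuned_bundle.cv_reports:
            for name in ("accuracy", "precision", "recall", "f1", "macro_auroc"):
                assert 0.0 <= report[name] <= 1.0

    def test_search_best_so_far_monotone(self, tuned_bundle):
        bests = [e.best_so_far for e in tuned_bundle.search_history]
        assert bests == sorted(bests)

    def test_same_seed_reproduces_best_configuration(self, separable_dataset):
        runs = [
            train_best_classifier(
                separable_dataset, k=4, init_points=2, n_iter=1, seed=3,
                early_stopping_rounds=None,
            )
            for _ in range(2)
        ]
        assert runs[0].config == runs[1].config
        assert [e.params for e in runs[0].search_history] == [
            e.params for e in runs[1].search_history
        ]
        assert runs[0].cv_reports == runs[1].cv_reports

    def test_separable_data_is_learned_accurately(self, tuned_bundle):
        summary = tuned_bundle.cv_summary()
        assert summary["accuracy"] >= 0.9
        assert summary["macro_auroc"] >= 0.95


class TestPredict:
    def test_probabilities_sum_to_one_per_record(self, tuned_bundle, separable_dataset):
        predictions = predict_species(tuned_bundle, separable_dataset.records[:5])
        for pred in predictions:
            assert math.isclose(sum(pred.probabilities.values()), 1.0, abs_tol=1e-6)

    def test_training_records_replay_to_their_own_species(
        self, tuned_bundle, separable_dataset
    ):
        predictions = predict_species(tuned_bundle, separable_dataset.records)
        correct = sum(
            p.species == r.species
            for p, r in zip(predictions, separable_dataset.records)
        )
        assert correct == len(separable_dataset)

    def test_short_sequence_flagged_unclassifiable(self, tuned_bundle):
        short = BarcodeRecord("tiny", "", "ACG")  # shorter than k=5
        normal = BarcodeRecord("ok", "", "ACGT" * 30)
        predictions = predict_species(tuned_bundle, [short, normal])
        assert predictions[0].unclassifiable and predictions[0].species is None
        assert not predictions[1].unclassifiable
        frame = predictions_frame(predictions)
        assert bool(frame.loc[0, "unclassifiable"]) is True

    def test_empty_record_list_rejected(self, tuned_bundle):
        with pytest.raises(ValueError):
            predict_species(tuned_bundle, [])


class TestBundlePersistence:
    def test_save_load_roundtrip_preserves_predictions(
        self, tuned_bundle, separable_dataset, tmp_path
    ):
        tuned_bundle.save(tmp_path / "model")
        loaded = ModelBundle.load(tmp_path / "model")
        assert loaded.label_map == tuned_bundle.label_map
        assert loaded.config == tuned_bundle.config
        assert loaded.k == tuned_bundle.k
        before = predict_species(tuned_bundle, separable_dataset.records[:6])
        after = predict_species(loaded, separable_dataset.records[:6])
        assert [p.species for p in before] == [p.species for p in after]


class TestSweep:
    def test_single_cell_equals_direct_cross_validation(self, separable_dataset):
        from barcodeid.features import encode_sequences

        result = sweep(separable_dataset, k_values=[4],
                       algorithms=["naive_bayes"], seed=0)
        X, _ = encode_sequences(separable_dataset.sequences, k=4)
        reports = cross_validate_estimator(
            lambda: make_classifier("naive_bayes", seed=0),
            X, np.asarray(separable_dataset.labels),
            separable_dataset.n_species, seed=0,
        )
        expected = float(np.mean([r["accuracy"] for r in reports]))
        cell = result.table.iloc[0]
        assert cell["accuracy"] == pytest.approx(expected)

    def test_scores_bounded_and_grid_complete(self, separable_dataset):
        result = sweep(separable_dataset, k_values=[3, 4],
                       algorithms=["naive_bayes", "random_forest"], seed=0)
        assert len(result.table) == 4
        finite = result.table[["accuracy", "macro_auroc"]].to_numpy()
        assert np.all((finite >= 0) & (finite <= 1))
        algorithm, k = result.best()
        assert algorithm in ("naive_bayes", "random_forest")
        assert k in (3, 4)

    def test_accuracy_degrades_as_within_species_noise_rises(self):
        accuracies = []
        for noise in (0.005, 0.20):
            config = SyntheticConfig(
                n_species=4, counts=[12] * 4, length_range=(150, 250),
                divergence=0.05, noise=noise, seed=17,
            )
            dataset, _ = generate_dataset(config)
            result = sweep(dataset, k_values=[5],
                           algorithms=["random_forest"], seed=17)
            accuracies.append(float(result.table["accuracy"].iloc[0]))
        assert accuracies[1] < accuracies[0]

    def test_empty_k_values_rejected(self, separable_dataset):
        with pytest.raises(ValueError):
            sweep(separable_dataset, k_values=[])
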