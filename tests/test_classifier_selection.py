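"""Dataset thresholds, the margin classifier, CV and SVM-RFE."""

import numpy as np
import pytest

from csrnai import (
    LabeledRecord,
    cross_validate,
    make_datasets,
    predict,
    svm_rfe,
    train,
)


def _records(activities):
    rng = np.random.default_rng(0)
    return [
        LabeledRecord(f"s{i}", "".join(rng.choice(list("ACGT"), size=19)), a)
        for i, a in enumerate(activities)
    ]


class TestMakeDatasets:
    def test_touching_cutoffs_label_everything(self):
        recs = _records(np.linspace(0, 1, 50))
        ds = make_datasets(recs, cutoff_sets=((0.5, 0.5),))[0]
        assert len(ds.records) == 50 and ds.n_excluded == 0

    def test_exclusion_fraction_matches_binomial(self):
        rng = np.random.default_rng(3)
        recs = _records(rng.uniform(0, 1, 1000))
        ds = make_datasets(recs, cutoff_sets=((0.3, 0.7),))[0]
        # expect 40% excluded; 4-sigma binomial band
        assert abs(ds.n_excluded - 400) < 4 * np.sqrt(1000 * 0.4 * 0.6)

    def test_invalid_cutoffs_rejected(self):
        recs = _records([0.1, 0.9])
        with pytest.raises(ValueError):
            make_datasets(recs, cutoff_sets=((0.7, 0.3),))

    def test_empty_class_rejected(self):
        recs = _records([0.9, 0.95, 0.99])
        with pytest.raises(ValueError, match="class empty"):
            make_datasets(recs, cutoff_sets=((0.3, 0.7),))


def _separable(n=40, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(-3, 0.5, (n // 2, 3)), rng.normal(3, 0.5, (n // 2, 3))])
    y = np.array([-1] * (n // 2) + [1] * (n // 2))
    return X, y


class TestTrain:
    def test_separable_clusters_fit_perfectly(self):
        X, y = _separable()
        labels, _ = predict(train(X, y), X)
        assert (labels == y).all()

    def test_label_flip_negates_weights(self):
        X, y = _separable()
        m1, m2 = train(X, y), train(X, -y)
        # agreement to the margin solver's own convergence tolerance (1e-3)
        assert np.allclose(m1.weights, -m2.weights, atol=1e-3)
        assert m1.bias == pytest.approx(-m2.bias, abs=1e-3)

    def test_duplicated_column_splits_weight(self):
        X, y = _separable()
        Xd = np.hstack([X, X[:, [0]]])
        m = train(Xd, y)
        assert m.weights[0] == pytest.approx(m.weights[3], rel=1e-4)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError, match="two classes"):
            train(X, np.ones(10))


class TestPredict:
    def test_zero_margin_called_negative(self):
        from csrnai import MarginModel
        model = MarginModel(weights=np.zeros(2), bias=0.0)
        labels, margins = predict(model, np.zeros((1, 2)))
        assert margins[0] == 0.0 and labels[0] == -1

    def test_partition_counts_conserved(self):
        X, y = _separable(60)
        model = train(X, y)
        rng = np.random.default_rng(5)
        cand = rng.normal(0, 3, (176, 3))
        labels, _ = predict(model, cand)
        assert (labels == 1).sum() + (labels == -1).sum() == 176

    def test_dimension_mismatch_rejected(self):
        X, y = _separable()
        with pytest.raises(ValueError, match="dimension"):
            predict(train(X, y), np.zeros((2, 7)))


class TestCrossValidate:
    def test_uninformative_features_near_majority_rate(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(200, 5))
        y = np.where(np.arange(200) < 120, 1, -1)  # 60% majority
        acc = cross_validate(X, y, folds=5, seed=1)
        assert abs(acc - 0.6) < 0.12

    def test_perfect_single_feature(self):
        rng = np.random.default_rng(2)
        y = np.where(rng.random(100) < 0.5, 1, -1)
        X = np.column_stack([y * 2.0, rng.normal(size=100)])
        assert cross_validate(X, y, folds=5, seed=0) == pytest.approx(1.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 4))
        y = np.where(X[:, 0] + rng.normal(0, 1, 80) > 0, 1, -1)
        assert cross_validate(X, y, seed=9) == cross_validate(X, y, seed=9)


class TestSvmRfe:
    @pytest.fixture(scope="class")
    def planted(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(400, 100))
        beta = np.zeros(100)
        beta[:5] = [1.5, -1.2, 1.0, 0.8, -1.0]
        y = np.where(X @ beta + rng.normal(0, 1, 400) > 0, 1, -1)
        return X, y

    def test_ranking_is_a_permutation(self, planted):
        X, y = planted
        res = svm_rfe(X, y, folds=3, seed=0)
        assert sorted(res.ranking) == list(range(100))
        assert set(res.selected) <= set(range(100))
        assert len(res.cv_accuracy_path) == len(res.n_features_path)

    def test_recovers_planted_informative_features(self, planted):
        X, y = planted
        res = svm_rfe(X, y, folds=3, seed=0)
        assert len(set(res.selected) & set(range(5))) >= 4

    def test_selection_beats_full_space(self, planted):
        X, y = planted
        res = svm_rfe(X, y, folds=3, seed=0)
        full = res.cv_accuracy_path[0]
        assert max(res.cv_accuracy_path) >= full

    def test_deterministic_and_records_fold_hashes(self, planted):
        X, y = planted
        a = svm_rfe(X, y, folds=3, seed=5)
        b = svm_rfe(X, y, folds=3, seed=5)
        assert a.ranking == b.ranking and a.selected == b.selected
        assert a.cv_accuracy_path == b.cv_accuracy_path
        assert len(a.fold_train_hashes) == 3 and a.fold_train_hashes == b.fold_train_hashes
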