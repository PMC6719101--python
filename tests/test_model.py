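"""Feature selection, classifier contracts, and the evaluation protocol."""

import numpy as np
import pytest

from cravesense.core import ValidationError
from cravesense.model import (CDNNClassifier, ClassifierSpec, CLASSIFIER_NAMES,
                              evaluate_cohort, evaluate_subject, fisher_score,
                              select_features, train_classifier)
from .conftest import make_gaussian_features


def test_fisher_score_hand_computation():
    X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
    y = np.array([0, 0, 0, 1, 1, 1])
    # class means 2 and 5, sample variances 1 and 1 -> 9 / 2
    assert fisher_score(X, y)[0] == pytest.approx(4.5)


def test_fisher_score_degenerate_cases():
    y = np.array([0, 0, 1, 1])
    same_means = np.array([[1.0], [3.0], [1.0], [3.0]])
    assert fisher_score(same_means, y)[0] == 0.0
    zero_var = np.array([[0.0], [0.0], [1.0], [1.0]])
    assert fisher_score(zero_var, y)[0] > 1e10  # epsilon-guarded, ranked top
    with pytest.raises(ValidationError):
        fisher_score(np.zeros((4, 2)), np.zeros(4))
    # NaNs are excluded pairwise, not propagated
    with_nan = np.array([[1.0], [np.nan], [4.0], [5.0]])
    assert np.isfinite(fisher_score(with_nan, y)[0])


def test_select_features_order_and_tie_break():
    scores = np.array([0.1, 0.9, 0.5, 0.9])
    assert select_features(scores, 2) == [1, 3]  # tie -> lower index first
    assert select_features(np.array([3.0, 1.0, 2.0]), 2) == [0, 2]
    with pytest.raises(ValidationError):
        select_features(scores, 0)


def test_knn_unanimous_neighbourhood():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(0, 0.1, size=(17, 2)),
                   rng.normal(10, 0.1, size=(3, 2))])
    y = np.array([0] * 17 + [1] * 3)
    clf = train_classifier(ClassifierSpec("knn"), X, y)
    assert clf.predict([[0.0, 0.0]])[0] == 0


def test_knn_k_larger_than_training_set_errors():
    with pytest.raises(ValidationError, match="kNN"):
        train_classifier(ClassifierSpec("knn"), np.zeros((5, 1)),
                         np.array([0, 1, 0, 1, 0]))


def test_cdnn_query_at_class_centroid_wins():
    X = np.array([[-1.0, 0.0], [1.0, 0.0], [0.0, 1.0],
                  [4.0, 4.0], [6.0, 4.0], [5.0, 5.0]])
    y = np.array([0, 0, 0, 1, 1, 1])
    clf = CDNNClassifier().fit(X, y)
    centroid0 = X[:3].mean(axis=0)
    assert clf.predict([centroid0])[0] == 0


def test_cdnn_tie_resolves_to_lower_label():
    X = np.array([[-1.0], [1.0]])
    y = np.array([0, 1])
    clf = CDNNClassifier().fit(X, y)
    assert clf.predict([[0.0]])[0] == 0  # displacements equal, counts equal


def test_lda_separable_1d_training_accuracy():
    X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
    y = np.array([0, 0, 0, 1, 1, 1])
    clf = train_classifier(ClassifierSpec("lda"), X, y)
    assert np.array_equal(clf.predict(X), y)


def test_protocol_structure_and_selection_counts():
    feats = make_gaussian_features(seed=1)
    for name, k_expected in (("svm_rbf", 2), ("knn", 1)):
        res = evaluate_subject(feats, ClassifierSpec(name), cv_seed=0)
        by_cond = {r.condition: r for r in res}
        cv = by_cond["cross_validation"]
        assert cv.fold_sizes == [(30, 6)] * 6
        assert len(cv.fold_accuracies) == 6
        assert len(cv.selected_features) == 6  # refit per fold
        assert by_cond["tr_day1"].n_train == 36
        assert by_cond["tr_day2"].n_train == 36
        assert by_cond["tr_day1_day2"].n_train == 72
        for r in res:
            assert r.n_test == 36
            assert all(len(sel) == k_expected for sel in r.selected_features)
            assert 0.0 <= r.accuracy <= 100.0


def test_informative_feature_is_selected_and_classified():
    feats = make_gaussian_features(seed=2, effect=4.0)
    res = evaluate_subject(feats, ClassifierSpec("lda"), cv_seed=0)
    for r in res:
        assert r.accuracy >= 90.0
        for sel in r.selected_features:
            assert FEATURE_NAME_AT_3 in sel


FEATURE_NAME_AT_3 = "mRR"  # canonical name of feature column index 3


def test_accuracy_invariant_to_affine_feature_rescaling():
    feats = make_gaussian_features(seed=3, effect=2.0)
    base = {}
    for name in ("svm_rbf", "knn", "cdnn", "lda"):
        res = evaluate_subject(feats, ClassifierSpec(name), cv_seed=0)
        base[name] = [r.accuracy for r in res]
    scaled = make_gaussian_features(seed=3, effect=2.0)
    for sid in scaled.X:
        scaled.X[sid] = scaled.X[sid].copy()
        scaled.X[sid][:, 3] = 10.0 * scaled.X[sid][:, 3] - 7.0
    for name, accs in base.items():
        res = evaluate_subject(scaled, ClassifierSpec(name), cv_seed=0)
        assert [r.accuracy for r in res] == accs


def test_missing_values_are_imputed_not_fatal():
    feats = make_gaussian_features(seed=4, effect=3.0)
    for sid in feats.X:
        feats.X[sid] = feats.X[sid].copy()
        feats.X[sid][::7, 5] = np.nan
    res = evaluate_subject(feats, ClassifierSpec("svm_rbf"), cv_seed=0)
    assert all(np.isfinite(r.accuracy) for r in res)


def test_cohort_summary_shape_and_single_subject_degeneracy():
    feats = make_gaussian_features(seed=5)
    per_subject, summary = evaluate_cohort([feats])
    assert set(summary.classifier) == set(CLASSIFIER_NAMES)
    assert len(summary) == 5 * 4
    assert (summary["iqr"] == 0.0).all()  # one subject -> degenerate IQR
    merged = summary.merge(per_subject, on=["classifier", "condition"])
    assert np.allclose(merged["median"], merged["accuracy"])
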