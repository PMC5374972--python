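"""Base classifiers, probability outputs and the binary-relevance stage."""

import numpy as np
import pytest

from ecfuse.classification import (
    LabelVector,
    predict_proba,
    predict_single_label,
    train_multi_label,
    train_probability_base_multilabel,
    train_single_label,
)
from ecfuse.sequence_similarity import ClassProbabilityVector

from oracles import knn_proba_oracle


def _blobs(rng, n_per_class=20, n_classes=3, spread=0.3):
    centers = rng.normal(scale=10.0, size=(n_classes, 4))
    X, y = [], []
    for c in range(n_classes):
        X.append(centers[c] + rng.normal(scale=spread, size=(n_per_class, 4)))
        y.extend([c + 1] * n_per_class)
    return np.vstack(X), np.array(y)


class TestSingleLabel:
    @pytest.mark.parametrize("method", ["svm", "nn"])
    def test_separable_blobs_classified_perfectly(self, method, rng):
        X, y = _blobs(rng)
        hold = rng.random(len(y)) < 0.25
        model = train_single_label(X[~hold], y[~hold], method)
        probs = predict_proba(model, X[hold])
        pred = np.array([predict_single_label(p) for p in probs])
        assert (pred == y[hold]).all()

    def test_prototype_limit_nn(self):
        X = np.eye(6)
        y = np.arange(1, 7)
        model = train_single_label(X, y, "nn")
        probs = predict_proba(model, X)
        for i, p in enumerate(probs):
            assert p.values[i] == 1.0  # exact hit: full mass on the prototype

    def test_nn_probabilities_match_bruteforce_knn(self, rng):
        X, y = _blobs(rng, n_per_class=15, n_classes=6, spread=3.0)
        queries = rng.normal(scale=8.0, size=(10, 4))
        model = train_single_label(X, y, "nn", nn_k=3)
        probs = np.vstack([p.values for p in predict_proba(model, queries)])
        expected = knn_proba_oracle(X, y, queries, k=3)
        np.testing.assert_allclose(probs, expected, atol=1e-12)

    def test_probability_rows_sum_to_one(self, rng):
        X, y = _blobs(rng, n_classes=4)
        for method in ("svm", "nn"):
            model = train_single_label(X, y, method)
            probs = predict_proba(model, rng.normal(size=(7, 4)))
            for p in probs:
                assert p.values.sum() == pytest.approx(1.0, abs=1e-9)
                assert len(p) == 6

    def test_absent_classes_get_zero_probability(self, rng):
        X, y = _blobs(rng, n_classes=3)  # classes 1..3 only
        model = train_single_label(X, y, "nn")
        probs = predict_proba(model, rng.normal(size=(5, 4)))
        for p in probs:
            assert (p.values[3:] == 0).all()

    def test_argmax_agrees_with_hard_prediction(self, rng):
        X, y = _blobs(rng, n_classes=6, spread=4.0)
        queries = rng.normal(scale=8.0, size=(20, 4))
        for method in ("svm", "nn"):
            model = train_single_label(X, y, method)
            probs = predict_proba(model, queries)
            soft = np.array([predict_single_label(p) for p in probs])
            hard = model.estimator.predict(queries)
            assert (soft == hard).all()

    def test_single_class_training_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="single class"):
            train_single_label(X, np.ones(10, dtype=int), "svm")

    def test_nan_features_rejected(self):
        X = np.array([[0.0, np.nan], [1.0, 2.0]])
        with pytest.raises(ValueError, match="finite"):
            train_single_label(X, np.array([1, 2]), "nn")

    def test_signature_mismatch_rejected(self, rng):
        X, y = _blobs(rng)
        model = train_single_label(X, y, "nn")
        with pytest.raises(ValueError, match="signature"):
            predict_proba(model, rng.normal(size=(3, 5)))


class TestPredictSingleLabel:
    def test_plain_argmax(self):
        p = ClassProbabilityVector([0.1, 0.6, 0.1, 0.1, 0.05, 0.05])
        assert predict_single_label(p) == 2

    def test_tie_breaks_to_lowest_class(self):
        p = ClassProbabilityVector([0.5, 0.5, 0, 0, 0, 0])
        assert predict_single_label(p) == 1

    def test_matches_bruteforce_scan(self, rng):
        for _ in range(100):
            v = rng.dirichlet(np.ones(6))
            p = ClassProbabilityVector(v)
            expected = 1 + max(range(6), key=lambda i: (v[i], -i))
            assert predict_single_label(p) == expected

    def test_invariant_to_monotone_rescaling(self, rng):
        v = rng.dirichlet(np.ones(6))
        w = np.sqrt(v)
        p1 = predict_single_label(ClassProbabilityVector(v))
        p2 = 1 + int(np.argmax(w))
        assert p1 == p2


class TestMultiLabel:
    def _relevance_data(self, rng, n=1200, margin=0.05):
        # label j on iff probability j > 1/6; keep a margin around the
        # threshold so the rule is separable with finite samples
        P = rng.dirichlet(np.ones(6), size=n)
        clear = (np.abs(P - 1 / 6) > margin).all(axis=1)
        P = P[clear]
        Y = (P > 1 / 6).astype(int)
        keep = Y.sum(axis=1) > 0
        return P[keep], Y[keep]

    def test_separable_relevance_rule_is_learned(self, rng):
        P, Y = self._relevance_data(rng)
        split = len(P) * 3 // 4
        model = train_multi_label(P[:split], Y[:split], "svm")
        pred = model.predict(P[split:])
        assert (pred == Y[split:]).all(axis=1).mean() >= 0.95

    def test_fallback_one_hot_at_fused_argmax(self, rng):
        P, Y = self._relevance_data(rng)
        model = train_multi_label(P, Y, "nn")
        # far-away queries can produce all-zero relevance votes; force the
        # situation by zeroing the relevance models
        from ecfuse.classification import _Constant

        model.relevance_models = [_Constant(0)] * 6
        queries = rng.dirichlet(np.ones(6), size=8)
        pred = model.predict(queries)
        assert (pred.sum(axis=1) == 1).all()
        np.testing.assert_array_equal(pred.argmax(axis=1), queries.argmax(axis=1))

    def test_never_all_zero(self, rng):
        P, Y = self._relevance_data(rng)
        model = train_multi_label(P[:60], Y[:60], "nn")
        pred = model.predict(rng.dirichlet(np.ones(6), size=50))
        assert (pred.sum(axis=1) >= 1).all()

    def test_equals_independent_binary_models(self, rng):
        from sklearn.svm import SVC

        P, Y = self._relevance_data(rng)
        model = train_multi_label(P[:80], Y[:80], "svm", svm_c=10.0)
        pred = model.predict(P[80:])
        for j in range(6):
            ref = SVC(kernel="rbf", C=10.0, gamma="scale").fit(P[:80], Y[:80, j])
            expected = ref.predict(P[80:])
            rows = pred[:, j]
            # fallback rows may deviate from the raw binary output
            fallback = pred.sum(axis=1) == 1
            mask = ~(fallback & (expected == 0))
            np.testing.assert_array_equal(rows[mask], expected[mask])

    def test_zero_positive_class_warns_and_predicts_zero(self, rng):
        P, Y = self._relevance_data(rng)
        Y = Y.copy()
        Y[:, 5] = 0
        Y[Y.sum(axis=1) == 0, 0] = 1
        with pytest.warns(UserWarning, match="class 6"):
            model = train_multi_label(P, Y, "svm")
        pred = model.predict(P)
        assert (pred[:, 5] == 0).all()

    def test_all_zero_true_row_rejected(self, rng):
        P = rng.dirichlet(np.ones(6), size=4)
        Y = np.zeros((4, 6), dtype=int)
        with pytest.raises(ValueError, match="no positive"):
            train_multi_label(P, Y, "svm")


class TestMultiLabelProbabilityBase:
    def test_reduces_to_informative_probabilities(self, rng):
        X, y = _blobs(rng, n_per_class=15, n_classes=6, spread=0.5)
        Y = np.zeros((len(y), 6), dtype=int)
        Y[np.arange(len(y)), y - 1] = 1
        for method in ("svm", "nn"):
            model = train_probability_base_multilabel(X, Y, method)
            probs = np.vstack([p.values for p in predict_proba(model, X)])
            assert (probs.argmax(axis=1) + 1 == y).mean() > 0.95
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)


class TestLabelVector:
    def test_classes_listing(self):
        lv = LabelVector([1, 0, 0, 1, 0, 0])
        assert lv.classes == [1, 4]

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            LabelVector([2, 0, 0, 0, 0, 0])
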