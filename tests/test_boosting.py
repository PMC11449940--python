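import json
import math

import numpy as np
import pytest

from pulseaf import (AdaBoostM1Classifier, feature_importance, load_model,
                     save_model, simulate_sinus, train_adaboost)
from pulseaf.boosting import (PERFECT_VOTE_WEIGHT, DecisionNode, WeakLearner,
                              _fit_tree)


def naive_adaboost_m1(X, y, rounds, max_depth):
    """Independent reference of the AdaBoost.M1 recursion.

    Uses the same deterministic weak-learner fitter but re-derives the
    weight updates and final vote from first principles (beta form,
    un-normalized weights, explicit per-class vote sums).
    """
    n = len(y)
    w = [1.0 / n] * n
    learners = []
    for _ in range(rounds):
        tree = _fit_tree(X, y, np.array(w), max_depth)
        pred = [tree.predict_one(row) for row in X]
        eps = sum(wi for wi, p, t in zip(w, pred, y) if p != t)
        if eps >= 0.5:
            break
        if eps == 0:
            learners.append((tree, PERFECT_VOTE_WEIGHT))
            break
        beta = eps / (1 - eps)
        learners.append((tree, math.log(1 / beta)))
        w = [wi * beta if p == t else wi for wi, p, t in zip(w, pred, y)]
        s = sum(w)
        w = [wi / s for wi in w]

    def predict(X):
        out = []
        for row in X:
            vote = {0: 0.0, 1: 0.0}
            for tree, alpha in learners:
                vote[tree.predict_one(row)] += alpha
            out.append(1 if vote[1] > vote[0] else 0)
        return np.array(out)

    return predict


class TestTraining:
    def test_separable_1d_single_stump(self):
        rng = np.random.default_rng(0)
        cv = np.concatenate([rng.uniform(0.0, 0.05, 30), rng.uniform(0.1, 0.2, 30)])
        X = cv[:, None]
        y = np.array([0] * 30 + [1] * 30)
        est = AdaBoostM1Classifier(n_estimators=50, max_depth=1).fit(X, y)
        assert len(est.learners_) == 1
        assert est.errors_ == [0.0]
        assert est.score(X, y) == 1.0

    def test_xor_solved_within_ten_rounds_depth2(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        y = np.array([0, 1, 1, 0])
        est = AdaBoostM1Classifier(n_estimators=10, max_depth=2).fit(X, y)
        np.testing.assert_array_equal(est.predict(X), y)

    def test_accepted_rounds_all_below_half_error(self, toy_table):
        X, y = toy_table
        est = AdaBoostM1Classifier(n_estimators=30, max_depth=1).fit(X, y)
        assert all(e < 0.5 for e in est.errors_)

    def test_training_error_bound(self, toy_table):
        # boosting guarantee: train error <= prod 2 sqrt(eps (1 - eps))
        X, y = toy_table
        est = AdaBoostM1Classifier(n_estimators=30, max_depth=1).fit(X, y)
        bound = np.prod([2 * math.sqrt(e * (1 - e)) for e in est.errors_ if e > 0])
        train_err = 1.0 - est.score(X, y)
        assert train_err <= bound + 1e-12

    def test_single_class_rejected(self):
        X = np.ones((5, 2))
        with pytest.raises(ValueError):
            AdaBoostM1Classifier().fit(X, np.zeros(5))

    def test_nonfinite_rejected(self):
        X = np.array([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError):
            AdaBoostM1Classifier().fit(X, [0, 1])


class TestPrediction:
    def test_single_learner_equals_tree(self, toy_table):
        X, y = toy_table
        est = AdaBoostM1Classifier(n_estimators=1, max_depth=2).fit(X, y)
        tree = est.learners_[0].tree
        manual = np.array([tree.predict_one(row) for row in X])
        np.testing.assert_array_equal(est.predict(X), est.classes_[manual])

    def test_margin_in_unit_interval(self, toy_table):
        X, y = toy_table
        est = AdaBoostM1Classifier(n_estimators=20, max_depth=1).fit(X, y)
        m = est.decision_function(X)
        assert np.all(m >= -1) and np.all(m <= 1)

    def test_leaf_flip_negates_margin(self, toy_table):
        X, y = toy_table
        est = AdaBoostM1Classifier(n_estimators=10, max_depth=1).fit(X, y)
        flipped = AdaBoostM1Classifier.from_dict(est.to_dict())

        def flip(node):
            if node.leaf is not None:
                node.leaf = 1 - node.leaf
            else:
                flip(node.left)
                flip(node.right)

        for lr in flipped.learners_:
            flip(lr.tree)
        np.testing.assert_allclose(flipped.decision_function(X),
                                   -est.decision_function(X), atol=1e-12)

    def test_tie_margin_goes_negative_class(self):
        # two learners with equal weights voting oppositely -> margin 0
        t0 = DecisionNode(leaf=0)
        t1 = DecisionNode(leaf=1)
        est = AdaBoostM1Classifier()
        est.classes_ = np.array(["NON_AFIB", "AFIB"])
        est.feature_names_ = None
        est.learners_ = [WeakLearner(t0, 1.0), WeakLearner(t1, 1.0)]
        est.errors_ = [0.25, 0.25]
        est.n_features_in_ = 2
        X = np.zeros((3, 2))
        assert np.all(est.decision_function(X) == 0.0)
        assert np.all(est.predict(X) == "NON_AFIB")

    def test_schema_mismatch_names_columns(self, default_model):
        import pandas as pd
        bad = pd.DataFrame({"not_a_feature": [1.0]})
        with pytest.raises(ValueError, match="missing"):
            default_model.predict(bad)


class TestOracles:
    def test_agrees_with_sklearn_adaboost(self, toy_table):
        # SAMME with two classes is AdaBoost.M1; independent implementation
        # and independent weak learners must agree on a clean toy table
        sklearn = pytest.importorskip("sklearn.ensemble")
        from sklearn.tree import DecisionTreeClassifier

        X, y = toy_table
        mine = AdaBoostM1Classifier(n_estimators=25, max_depth=2).fit(X, y)
        ref = sklearn.AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=2, random_state=0),
            n_estimators=25, random_state=0,
        ).fit(X, y)
        agree = np.mean(mine.predict(X) == ref.predict(X))
        assert agree == 1.0

    def test_agrees_with_naive_m1_recursion(self, toy_table):
        X, y = toy_table
        mine = AdaBoostM1Classifier(n_estimators=15, max_depth=1).fit(X, y)
        ref_predict = naive_adaboost_m1(X, y, rounds=15, max_depth=1)
        np.testing.assert_array_equal(mine.predict(X), mine.classes_[ref_predict(X)])

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        est = AdaBoostM1Classifier(n_estimators=7, max_depth=3)
        c = clone(est)
        assert c.get_params() == est.get_params()


class TestImportance:
    def test_scores_normalized(self, default_model):
        imp = feature_importance(default_model)
        assert all(v >= 0 for v in imp.values())
        assert sum(imp.values()) == pytest.approx(1.0)

    def test_single_feature_ensemble_scores_one(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([rng.uniform(0, 1, 40), np.zeros(40)])
        y = (X[:, 0] > 0.5).astype(int)
        est = AdaBoostM1Classifier(n_estimators=5, max_depth=1).fit(X, y)
        assert est.feature_importances_[0] == pytest.approx(1.0)
        assert est.feature_importances_[1] == 0.0

    def test_cstd_features_lead_on_default_run(self, default_model):
        # mirrors the design premise: the clustered-SD features carry the
        # discrimination between AFib and patterned ectopy
        imp = feature_importance(default_model)
        top2 = sorted(imp, key=imp.get, reverse=True)[:2]
        assert any(k.startswith("cstd") for k in top2)


class TestSerialization:
    def test_round_trip_identical_margins(self, default_model, tmp_path):
        path = tmp_path / "model.json"
        save_model(default_model, path)
        loaded = load_model(path)
        rng = np.random.default_rng(0)
        X = rng.uniform(0.0, 2.0, size=(100, default_model.n_features_in_))
        np.testing.assert_array_equal(loaded.decision_function(X),
                                      default_model.decision_function(X))

    def test_corrupted_file_raises(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text("{not json")
        with pytest.raises(ValueError, match="corrupted"):
            load_model(p)

    def test_version_mismatch_raises(self, default_model, tmp_path):
        d = default_model.to_dict()
        d["format_version"] = "something-else"
        p = tmp_path / "v.json"
        p.write_text(json.dumps(d))
        with pytest.raises(ValueError, match="format"):
            load_model(p)

    def test_retrain_same_inputs_identical_file(self, toy_table, tmp_path):
        X, y = toy_table
        p1, p2 = tmp_path / "m1.json", tmp_path / "m2.json"
        save_model(AdaBoostM1Classifier(n_estimators=10).fit(X, y), p1)
        save_model(AdaBoostM1Classifier(n_estimators=10).fit(X, y), p2)
        assert p1.read_bytes() == p2.read_bytes()


def test_margin_monotone_in_jitter(default_model):
    """Mean AFib margin should not decrease as sinus jitter grows.

    The sweep stays within the modeled regime (coefficient of variation up
    to ~0.13): far beyond it, extreme spreads start splitting into several
    clusters, which lowers the clustered-SD features again.
    """
    from pulseaf.features import compute_features

    jitters = [0.005, 0.02, 0.05, 0.1]
    means = []
    for j in jitters:
        margins = []
        for seed in range(60):
            s = simulate_sinus(22, 0.75, j, seed=seed)
            fv = compute_features(s)
            margins.append(default_model.decision_function(fv.as_array()[None, :])[0])
        means.append(np.mean(margins))
    diffs = np.diff(means)
    assert np.all(diffs > -0.05)  # non-decreasing up to Monte-Carlo noise
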