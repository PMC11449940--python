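"""AdaBoost.M1 over shallow deterministic decision trees.

The screening classifier is a boosted ensemble of small decision trees on the
distributional interval features. AdaBoost.M1 maintains a weight per training
example: each round fits a weak learner to the weighted sample, computes its
weighted error ``eps``, down-weights the examples it got right by
``beta = eps / (1 - eps)``, renormalizes, and gives the learner a vote weight
``ln(1 / beta)``. Rounds with ``eps >= 0.5`` terminate boosting; a perfect
round (``eps == 0``) receives a capped vote weight and also terminates.

The weak learners are depth-limited CART-style trees fit by exhaustive search
with weighted Gini impurity. Tree fitting is fully deterministic: features
are scanned in schema order, candidate thresholds are midpoints between
adjacent sorted distinct values, and ties are broken by the first split
found. Prediction is a weighted vote; the signed margin
``(votes_for_positive - votes_against) / total_votes`` lies in [-1, 1] and
exact ties (margin 0) are classified as the negative class — a screening
tool prefers specificity on ties.

Ensembles serialize to structural JSON (no opaque binary) and round-trip
exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from .features import FEATURE_NAMES, FEATURE_SCHEMA_VERSION, FeatureVector

__all__ = [
    "DecisionNode",
    "WeakLearner",
    "AdaBoostM1Classifier",
    "BoostedEnsemble",
    "train_adaboost",
    "predict",
    "feature_importance",
    "save_model",
    "load_model",
    "MODEL_FORMAT_VERSION",
]

MODEL_FORMAT_VERSION = "pulseaf-model-1"

#: vote weight assigned to a weak learner with zero weighted error
PERFECT_VOTE_WEIGHT = math.log(1e6)


# ---------------------------------------------------------------------------
# weak learner


@dataclass
class DecisionNode:
    """One node of a decision tree.

    Internal nodes hold ``(feature, threshold)`` and route x[feature] <=
    threshold to ``left``; leaves hold a class index (0 or 1) in ``leaf``.
    """

    feature: int = -1
    threshold: float = 0.0
    left: "DecisionNode | None" = None
    right: "DecisionNode | None" = None
    leaf: int | None = None
    impurity_decrease: float = 0.0

    def predict_one(self, x: np.ndarray) -> int:
        node = self
        while node.leaf is None:
            node = node.left if x[node.feature] <= node.threshold else node.right
        return node.leaf

    def to_dict(self) -> dict[str, Any]:
        if self.leaf is not None:
            return {"leaf": int(self.leaf)}
        return {
            "feature": int(self.feature),
            "threshold": float(self.threshold),
            "impurity_decrease": float(self.impurity_decrease),
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "DecisionNode":
        if "leaf" in d:
            return cls(leaf=int(d["leaf"]))
        return cls(
            feature=int(d["feature"]),
            threshold=float(d["threshold"]),
            impurity_decrease=float(d.get("impurity_decrease", 0.0)),
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


def _gini(w_pos: float, w_neg: float) -> float:
    tot = w_pos + w_neg
    if tot <= 0:
        return 0.0
    p = w_pos / tot
    return 2.0 * p * (1.0 - p)


def _best_split(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, order: list[np.ndarray]
) -> tuple[int, float, float] | None:
    """Exhaustive weighted-Gini split search.

    Returns (feature, threshold, impurity_decrease) or None when no feature
    has two distinct values. Features are scanned in column order; thresholds
    are midpoints between adjacent distinct sorted values; ties keep the
    first split found (strict improvement required to replace). A zero-gain
    best split is still returned — on parity-style problems (XOR) the gain
    only materializes one level deeper.
    """
    w_pos_tot = float(w[y == 1].sum())
    w_neg_tot = float(w.sum()) - w_pos_tot
    parent = _gini(w_pos_tot, w_neg_tot) * (w_pos_tot + w_neg_tot)
    best: tuple[int, float, float] | None = None
    best_score = np.inf
    for j in range(X.shape[1]):
        idx = order[j]
        xv = X[idx, j]
        wv = w[idx]
        yv = y[idx]
        cum_pos = np.cumsum(wv * (yv == 1))
        cum_all = np.cumsum(wv)
        # candidate split after position i (0-based): left = first i+1 rows
        distinct = np.where(np.diff(xv) > 0)[0]
        if distinct.size == 0:
            continue
        lp = cum_pos[distinct]
        la = cum_all[distinct]
        rp = w_pos_tot - lp
        ra = (w_pos_tot + w_neg_tot) - la
        with np.errstate(divide="ignore", invalid="ignore"):
            g_left = np.where(la > 0, 2.0 * lp * (la - lp) / la, 0.0)
            g_right = np.where(ra > 0, 2.0 * rp * (ra - rp) / ra, 0.0)
        scores = g_left + g_right
        k = int(np.argmin(scores))  # first minimum: lowest-threshold tie-break
        if scores[k] < best_score - 1e-15:
            best_score = float(scores[k])
            i = distinct[k]
            thr = 0.5 * (xv[i] + xv[i + 1])
            best = (j, float(thr), float(parent - best_score))
    return best


def _majority(y: np.ndarray, w: np.ndarray) -> int:
    """Weighted majority class; exact ties go to the negative class."""
    w_pos = float(w[y == 1].sum())
    w_neg = float(w.sum()) - w_pos
    return 1 if w_pos > w_neg else 0


def _fit_tree(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, max_depth: int
) -> DecisionNode:
    def build(rows: np.ndarray, depth: int) -> DecisionNode:
        ys, ws = y[rows], w[rows]
        if depth >= max_depth or np.all(ys == ys[0]):
            return DecisionNode(leaf=_majority(ys, ws))
        Xs = X[rows]
        order = [np.argsort(Xs[:, j], kind="stable") for j in range(X.shape[1])]
        split = _best_split(Xs, ys, ws, order)
        if split is None:
            return DecisionNode(leaf=_majority(ys, ws))
        j, thr, dec = split
        mask = Xs[:, j] <= thr
        node = DecisionNode(feature=j, threshold=thr, impurity_decrease=dec)
        node.left = build(rows[mask], depth + 1)
        node.right = build(rows[~mask], depth + 1)
        return node

    return build(np.arange(X.shape[0]), 0)


@dataclass
class WeakLearner:
    """A depth-limited decision tree with its boosting vote weight."""

    tree: DecisionNode
    vote_weight: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.array([self.tree.predict_one(row) for row in X])


# ---------------------------------------------------------------------------
# estimator


class AdaBoostM1Classifier:
    """AdaBoost.M1 ensemble of shallow deterministic decision trees.

    Scikit-learn-compatible binary classifier. ``y`` may be any two labels;
    the positive class (the one flagged by a positive margin) is
    ``positive_label`` if given, else the lexicographically larger class.

    Parameters
    ----------
    n_estimators : int
        Maximum number of boosting rounds (default 50).
    max_depth : int
        Weak-learner tree depth (default 2).
    positive_label : label or None
        Which class counts as positive for the margin sign.
    random_state : int or None
        Recorded in metadata; the algorithm itself is deterministic given the
        input order, so this does not affect the fit.

    Attributes
    ----------
    learners_ : list of WeakLearner
        Fitted weak learners in boosting order, with vote weights.
    classes_ : ndarray of shape (2,)
        Class labels, negative class first.
    errors_ : list of float
        Weighted error of each accepted round.
    feature_importances_ : ndarray
        Vote-weighted impurity decreases per feature, normalized to sum 1.
    """

    def __init__(
        self,
        n_estimators: int = 50,
        max_depth: int = 2,
        positive_label: Any = None,
        random_state: int | None = None,
        feature_names: Sequence[str] | None = None,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.positive_label = positive_label
        self.random_state = random_state
        self.feature_names = feature_names

    # -- sklearn plumbing ---------------------------------------------------

    _param_names = ("n_estimators", "max_depth", "positive_label",
                    "random_state", "feature_names")

    def get_params(self, deep: bool = True) -> dict[str, Any]:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params: Any) -> "AdaBoostM1Classifier":
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- fitting ------------------------------------------------------------

    def _validate_X(self, X) -> np.ndarray:
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            names = getattr(self, "feature_names_", None)
            if names is not None:
                missing = [c for c in names if c not in X.columns]
                extra = [c for c in X.columns if c not in names]
                if missing:
                    raise ValueError(f"feature schema mismatch: missing {missing}, extra {extra}")
                X = X[list(names)]
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return X

    def fit(self, X, y) -> "AdaBoostM1Classifier":
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            self.feature_names_ = list(X.columns)
        elif self.feature_names is not None:
            self.feature_names_ = list(self.feature_names)
        else:
            self.feature_names_ = None
        Xv = self._validate_X(X)
        y = np.asarray(y)
        if Xv.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if Xv.shape[0] < 2:
            raise ValueError("need at least 2 training rows")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"need exactly 2 classes in y, got {classes.size}")
        if self.positive_label is not None:
            if self.positive_label not in classes:
                raise ValueError(f"positive_label {self.positive_label!r} not in y")
            neg = classes[classes != self.positive_label][0]
            classes = np.array([neg, self.positive_label])
        self.classes_ = classes
        ybin = (y == classes[1]).astype(int)

        n = Xv.shape[0]
        w = np.full(n, 1.0 / n)
        self.learners_: list[WeakLearner] = []
        self.errors_: list[float] = []
        for _ in range(self.n_estimators):
            tree = _fit_tree(Xv, ybin, w, self.max_depth)
            pred = np.array([tree.predict_one(row) for row in Xv])
            miss = pred != ybin
            eps = float(w[miss].sum())
            if eps >= 0.5:
                if not self.learners_:
                    # accept a single weak-but-informative learner is not
                    # possible; a majority-vote stump at eps >= 0.5 carries
                    # no information, so refuse with a clear error
                    raise ValueError("no weak learner better than chance; check features")
                break
            if eps == 0.0:
                self.learners_.append(WeakLearner(tree, PERFECT_VOTE_WEIGHT))
                self.errors_.append(eps)
                break
            beta = eps / (1.0 - eps)
            self.learners_.append(WeakLearner(tree, math.log(1.0 / beta)))
            self.errors_.append(eps)
            w[~miss] *= beta
            w /= w.sum()
        self._compute_importances(Xv.shape[1])
        self.n_features_in_ = Xv.shape[1]
        return self

    def _compute_importances(self, n_features: int) -> None:
        imp = np.zeros(n_features)

        def walk(node: DecisionNode, weight: float) -> None:
            if node.leaf is not None:
                return
            imp[node.feature] += weight * node.impurity_decrease
            walk(node.left, weight)
            walk(node.right, weight)

        for lr in self.learners_:
            walk(lr.tree, lr.vote_weight)
        total = imp.sum()
        self.feature_importances_ = imp / total if total > 0 else imp

    # -- prediction ---------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "learners_"):
            raise RuntimeError("classifier is not fitted")

    def decision_function(self, X) -> np.ndarray:
        """Signed vote margin in [-1, 1]; positive favors the positive class."""
        self._check_fitted()
        Xv = self._validate_X(X)
        total = sum(lr.vote_weight for lr in self.learners_)
        votes = np.zeros(Xv.shape[0])
        for lr in self.learners_:
            pred = lr.predict(Xv)
            votes += lr.vote_weight * (2.0 * pred - 1.0)
        return votes / total

    def predict(self, X) -> np.ndarray:
        margin = self.decision_function(X)
        # ties (margin exactly 0) go to the negative class
        return self.classes_[(margin > 0).astype(int)]

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        self._check_fitted()
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "feature_schema_version": FEATURE_SCHEMA_VERSION,
            "params": {"n_estimators": self.n_estimators, "max_depth": self.max_depth,
                       "random_state": self.random_state},
            "classes": [_json_scalar(c) for c in self.classes_],
            "feature_names": self.feature_names_,
            "rounds": len(self.learners_),
            "errors": self.errors_,
            "learners": [
                {"tree": lr.tree.to_dict(), "vote_weight": lr.vote_weight}
                for lr in self.learners_
            ],
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AdaBoostM1Classifier":
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format {d.get('format_version')!r}; "
                f"expected {MODEL_FORMAT_VERSION!r}"
            )
        if d.get("feature_schema_version") != FEATURE_SCHEMA_VERSION:
            raise ValueError(
                f"feature schema mismatch: model has {d.get('feature_schema_version')!r}, "
                f"this version uses {FEATURE_SCHEMA_VERSION!r}"
            )
        params = d["params"]
        est = cls(n_estimators=params["n_estimators"], max_depth=params["max_depth"],
                  random_state=params.get("random_state"))
        est.classes_ = np.array(d["classes"])
        est.feature_names_ = d.get("feature_names")
        est.errors_ = list(d["errors"])
        est.learners_ = [
            WeakLearner(DecisionNode.from_dict(l["tree"]), float(l["vote_weight"]))
            for l in d["learners"]
        ]
        n_feat = len(est.feature_names_) if est.feature_names_ else _max_feature(est.learners_) + 1
        est._compute_importances(n_feat)
        est.n_features_in_ = n_feat
        return est


def _max_feature(learners: Sequence[WeakLearner]) -> int:
    best = 0

    def walk(node: DecisionNode) -> None:
        nonlocal best
        if node.leaf is None:
            best = max(best, node.feature)
            walk(node.left)
            walk(node.right)

    for lr in learners:
        walk(lr.tree)
    return best


def _json_scalar(v: Any) -> Any:
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.str_):
        return str(v)
    return v


# ---------------------------------------------------------------------------
# functional surface

BoostedEnsemble = AdaBoostM1Classifier  # alias: the fitted ensemble object


def train_adaboost(
    features, labels, rounds: int = 50, max_depth: int = 2,
    seed: int | None = None, positive_label: Any = "AFIB",
) -> AdaBoostM1Classifier:
    """Fit an AdaBoost.M1 ensemble on a feature table.

    ``features`` is a DataFrame or 2-D array (one row per measurement);
    ``labels`` are binarized to ``positive_label`` vs rest before fitting.
    """
    labels = np.asarray(labels)
    ybin = np.where(labels == positive_label, "AFIB", "NON_AFIB")
    est = AdaBoostM1Classifier(n_estimators=rounds, max_depth=max_depth,
                               positive_label="AFIB", random_state=seed)
    return est.fit(features, ybin)


def predict(ensemble: AdaBoostM1Classifier, fv: FeatureVector) -> tuple[str, float]:
    """Classify one feature vector; returns (label, margin)."""
    if fv.schema_version != FEATURE_SCHEMA_VERSION:
        raise ValueError(
            f"schema mismatch: vector has {fv.schema_version!r}, "
            f"model expects {FEATURE_SCHEMA_VERSION!r}"
        )
    X = fv.as_array()[None, :]
    margin = float(ensemble.decision_function(X)[0])
    label = str(ensemble.classes_[1]) if margin > 0 else str(ensemble.classes_[0])
    return label, margin


def feature_importance(ensemble: AdaBoostM1Classifier) -> dict[str, float]:
    """Normalized vote-weighted impurity decrease per feature name."""
    ensemble._check_fitted()
    names = ensemble.feature_names_ or list(FEATURE_NAMES[: ensemble.n_features_in_])
    return {n: float(v) for n, v in zip(names, ensemble.feature_importances_)}


def save_model(ensemble: AdaBoostM1Classifier, path: str | Path) -> None:
    Path(path).write_text(json.dumps(ensemble.to_dict(), indent=1, sort_keys=True))


def load_model(path: str | Path) -> AdaBoostM1Classifier:
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"corrupted model file {path}: {e}") from e
    return AdaBoostM1Classifier.from_dict(d)
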