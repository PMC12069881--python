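"""Soft-voting ensemble for binary passenger-risk detection.

Six base classifiers — AdaBoost over a decision tree, Gaussian naive
Bayes, an RBF SVM and logistic regression, plus a random forest and an
MLP — are trained per subject per scenario on the 32-dimensional selected
wavelet features.  The ensemble averages the six risky-class
probabilities and flags risk when the mean reaches 0.5 (ties resolve to
"risky").  Balanced accuracy, the mean of sensitivity and specificity,
is the evaluation metric throughout because risky windows are the
minority class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

MEMBER_NAMES = ["AB-DT", "AB-GNB", "AB-SVM", "AB-LR", "RF", "MLP"]
N_SELECTED_FEATURES = 32


class BoostedMember(ClassifierMixin, BaseEstimator):
    """AdaBoost wrapper that degrades gracefully on hard small samples.

    AdaBoost refuses to fit when its first weak learner is no better than
    random; in that case the member falls back to the unboosted base
    classifier so the ensemble always keeps its six voters.
    """

    def __init__(self, booster: AdaBoostClassifier):
        self.booster = booster
        self.fitted_ = None
        self.fell_back_ = False

    def fit(self, X, y):
        try:
            self.fitted_ = clone(self.booster).fit(X, y)
        except ValueError:
            self.fitted_ = clone(self.booster.estimator).fit(X, y)
            self.fell_back_ = True
        return self

    @property
    def classes_(self):
        return self.fitted_.classes_

    def predict_proba(self, X):
        return self.fitted_.predict_proba(X)


@dataclass
class EnsembleSpec:
    """Hyperparameters of the six members; defaults are deliberately plain."""

    n_boost: int = 50
    tree_max_depth: int = 3
    svm_c: float = 1.0
    rf_trees: int = 100
    mlp_hidden: tuple[int, ...] = (64,)
    mlp_max_iter: int = 500

    def build(self, seed: int) -> dict[str, object]:
        rs = np.random.RandomState(seed)

        def s() -> int:
            return int(rs.randint(0, 2**31 - 1))

        members = {
            "AB-DT": BoostedMember(AdaBoostClassifier(
                DecisionTreeClassifier(max_depth=self.tree_max_depth,
                                       random_state=s()),
                n_estimators=self.n_boost, random_state=s())),
            "AB-GNB": BoostedMember(AdaBoostClassifier(
                GaussianNB(), n_estimators=self.n_boost, random_state=s())),
            "AB-SVM": BoostedMember(AdaBoostClassifier(
                SVC(C=self.svm_c, kernel="rbf", probability=True,
                    random_state=s()),
                n_estimators=self.n_boost, random_state=s())),
            "AB-LR": BoostedMember(AdaBoostClassifier(
                LogisticRegression(max_iter=1000),
                n_estimators=self.n_boost, random_state=s())),
            "RF": RandomForestClassifier(n_estimators=self.rf_trees,
                                         random_state=s()),
            "MLP": MLPClassifier(hidden_layer_sizes=self.mlp_hidden,
                                 max_iter=self.mlp_max_iter, random_state=s()),
        }
        # scale-sensitive members get a standardizing front end
        for name in ("AB-SVM", "AB-LR", "MLP"):
            members[name] = make_pipeline(StandardScaler(), members[name])
        return members


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def balanced_accuracy(counts: ConfusionCounts) -> float:
    """BA = (sensitivity + specificity) / 2."""
    if counts.tp + counts.fn == 0 or counts.tn + counts.fp == 0:
        raise ValueError("both classes must be present in the truth")
    sens = counts.tp / (counts.tp + counts.fn)
    spec = counts.tn / (counts.tn + counts.fp)
    return 0.5 * (sens + spec)


def ba_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    return balanced_accuracy(ConfusionCounts(
        tp=int(np.sum(y_pred & y_true)), tn=int(np.sum(~y_pred & ~y_true)),
        fp=int(np.sum(y_pred & ~y_true)), fn=int(np.sum(~y_pred & y_true))))


class RiskEnsemble:
    """The fitted six-member soft-voting detector."""

    def __init__(self, members: dict[str, object], seed: int,
                 threshold: float = 0.5):
        if len(members) != 6:
            raise ValueError("the ensemble has exactly 6 members")
        self.members = members
        self.seed = seed
        self.threshold = threshold

    def member_probabilities(self, X: np.ndarray) -> np.ndarray:
        """(n_members, n_samples) risky-class probabilities."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != N_SELECTED_FEATURES:
            raise ValueError(
                f"expected {N_SELECTED_FEATURES} selected features, got {X.shape[1]}")
        probs = []
        for name in MEMBER_NAMES:
            clf = self.members[name]
            pos = list(clf.classes_).index(True) if True in list(clf.classes_) \
                else int(np.argmax(clf.classes_))
            probs.append(clf.predict_proba(X)[:, pos])
        return np.stack(probs)

    def predict_soft(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Mean risky-class probability and the ≥-threshold decision."""
        p = self.member_probabilities(X).mean(axis=0)
        return p, p >= self.threshold

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_soft(X)[1]

    def model_card(self) -> dict:
        return {"members": MEMBER_NAMES, "voting": "soft",
                "threshold": self.threshold, "seed": self.seed}

    def save_card(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.model_card(), indent=2))


def train(features_32: np.ndarray, labels: np.ndarray,
          spec: EnsembleSpec | None = None, seed: int = 0) -> RiskEnsemble:
    """Fit all six members on the selected features."""
    X = np.asarray(features_32, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if np.unique(y).size < 2:
        raise ValueError("training set must contain both classes")
    spec = spec if spec is not None else EnsembleSpec()
    members = spec.build(seed)
    for clf in members.values():
        clf.fit(X, y)
    return RiskEnsemble(members, seed=seed)


def predict_soft(model: RiskEnsemble, feature_vector: np.ndarray):
    """Soft vote for a single 32-dim window: (p_risky, is_risky)."""
    p, k = model.predict_soft(np.atleast_2d(feature_vector))
    return float(p[0]), bool(k[0])


def cross_validated_predictions(
    features_32: np.ndarray, labels: np.ndarray,
    spec: EnsembleSpec | None = None, seed: int = 0, n_folds: int = 5,
) -> np.ndarray:
    """Held-out soft-vote probabilities via stratified k-fold."""
    X = np.asarray(features_32, dtype=float)
    y = np.asarray(labels, dtype=bool)
    spec = spec if spec is not None else EnsembleSpec()
    probs = np.zeros(y.size)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(X, y):
        model = train(X[tr], y[tr], spec, seed)
        probs[te] = model.predict_soft(X[te])[0]
    return probs


def cross_validated_ba(features_32, labels, spec=None, seed=0,
                       n_folds: int = 5, threshold: float = 0.5) -> float:
    p = cross_validated_predictions(features_32, labels, spec, seed, n_folds)
    return ba_from_predictions(labels, p >= threshold)


def permutation_pvalue(y_true: np.ndarray, y_pred: np.ndarray,
                       n_permutations: int = 10_000, seed: int = 0) -> float:
    """Permutation p-value for BA > chance with fixed held-out predictions.

    Labels are permuted against the predictions; the p-value is the
    fraction of permuted BAs at least as large as the observed one
    (add-one correction).
    """
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    obs = ba_from_predictions(y_true, y_pred)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(y_true)
        if ba_from_predictions(perm, y_pred) >= obs:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


@dataclass
class DetectionEvent:
    t: float
    p_risky: float
    k_fnirs: int


def online_detect(slices, model: RiskEnsemble, selector) -> list[DetectionEvent]:
    """Classify each emitted 5-s slice: featurize newest 4 s, select, vote.

    ``slices`` is the output of the preprocessing chain (HemoSlice list in
    emission order); returns one detection event per slice, the online
    k_fNIRS(t) gate signal.
    """
    from . import features as F

    events = []
    for s in slices:
        raw = F.window_features(s.feature_window())
        vec = selector.transform(raw[None])[0]
        p, k = predict_soft(model, vec)
        events.append(DetectionEvent(t=s.t_end, p_risky=p, k_fnirs=int(k)))
    return events
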