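"""The three probabilistic base classifiers and their hyperparameter policy.

The learners themselves are standard (scikit-learn); this module pins the
hyperparameter policy of the study design — a 1000-tree random forest with
sqrt-of-features splits, an RBF SVM tuned on a 2-D (C, γ) grid with [0, 1]
min–max scaling, and a 10-iteration boosted decision-tree ensemble — and
normalizes every learner's output into a common :class:`ClassifierOutput`
contract: a per-pixel probability row over the full class dictionary
(summing to 1) and the argmax label with ties broken to the lowest class
index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ClassifierSpec",
    "ClassifierOutput",
    "normalize_features",
    "resolve_hyperparams",
    "train_and_predict",
    "DEFAULT_SVM_GRID",
    "FAST_SVM_GRID",
    "KINDS",
]

KINDS = ("random_forest", "svm_rbf", "boosted_tree")

#: the classic libSVM search grid
DEFAULT_SVM_GRID = {
    "C": [2.0 ** e for e in range(-5, 16, 2)],
    "gamma": [2.0 ** e for e in range(-15, 4, 2)],
    "cv": 5,
}

#: coarse grid used by the experiment protocol (see evaluation module)
FAST_SVM_GRID = {
    "C": [2.0 ** e for e in (-1, 3, 7, 11)],
    "gamma": [2.0 ** e for e in (-7, -3, 1)],
    "cv": 3,
}


@dataclass(frozen=True)
class ClassifierSpec:
    """One base classifier: kind, hyperparameters, seed."""

    kind: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")


@dataclass
class ClassifierOutput:
    """Predicted label and per-class probability row per pixel.

    ``proba`` has one column per class in the full dictionary 1..K, each
    row summing to 1; ``labels`` is the per-row argmax (ties to the lowest
    class index).
    """

    labels: np.ndarray
    proba: np.ndarray

    def __post_init__(self):
        sums = self.proba.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("probability rows must sum to 1")
        if np.any(self.proba < -1e-12) or np.any(self.proba > 1 + 1e-12):
            raise ValueError("probabilities outside [0, 1]")

    @property
    def n_classes(self) -> int:
        return self.proba.shape[1]


def normalize_features(train: np.ndarray, apply: np.ndarray):
    """Per-feature min–max scaling fitted on the training rows only.

    Returns ``(train_scaled, apply_scaled, (mins, ranges))``.  Apply-set
    values outside the training span are NOT clipped and may leave [0, 1].
    A zero-range feature is mapped to constant 0 with a warning.
    """
    train = np.asarray(train, float)
    apply = np.asarray(apply, float)
    mins = train.min(axis=0)
    ranges = train.max(axis=0) - mins
    degenerate = ranges == 0
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} zero-range feature(s) mapped to constant 0",
            stacklevel=2)
    safe = np.where(degenerate, 1.0, ranges)
    tr = (train - mins) / safe
    ap = (apply - mins) / safe
    tr[:, degenerate] = 0.0
    ap[:, degenerate] = 0.0
    return tr, ap, (mins, ranges)


def _svm_grid_search(X: np.ndarray, y: np.ndarray, grid: dict, seed: int):
    """Pick (C, γ) by cross-validated accuracy; ties → smallest C then γ."""
    min_class = int(np.unique(y, return_counts=True)[1].min())
    cv = StratifiedKFold(n_splits=max(2, min(grid.get("cv", 5), min_class)),
                         shuffle=True, random_state=seed)
    best = (-np.inf, None, None)
    for c in sorted(grid["C"]):
        for g in sorted(grid["gamma"]):
            clf = SVC(kernel="rbf", C=c, gamma=g, random_state=seed)
            score = cross_val_score(clf, X, y, cv=cv).mean()
            if score > best[0] + 1e-12:  # strict improvement: earliest (C, γ) wins ties
                best = (score, c, g)
    return best[1], best[2], best[0]


def resolve_hyperparams(spec: ClassifierSpec, n_features: int,
                        train_X: np.ndarray | None = None,
                        train_y: np.ndarray | None = None) -> ClassifierSpec:
    """Fill in the study's hyperparameter policy for one classifier kind.

    random_forest → 1000 trees, ``floor(sqrt(n_features))`` split features
    (min 1); svm_rbf → (C, γ) maximizing cross-validated accuracy over a
    2-D grid (features are expected min–max scaled); boosted_tree → 10
    boosting iterations.  User-supplied hyperparams take precedence.
    """
    hp = dict(spec.hyperparams)
    if spec.kind == "random_forest":
        hp.setdefault("n_estimators", 1000)
        hp.setdefault("max_features", max(1, int(np.sqrt(n_features))))
    elif spec.kind == "boosted_tree":
        hp.setdefault("n_estimators", 10)
    elif spec.kind == "svm_rbf":
        if "C" not in hp or "gamma" not in hp:
            if train_X is None or train_y is None:
                raise ValueError("svm_rbf needs training data to tune (C, gamma)")
            if len(np.unique(train_y)) < 2:
                raise ValueError("single-class training set")
            grid = hp.pop("grid", DEFAULT_SVM_GRID)
            c, g, _ = _svm_grid_search(np.asarray(train_X, float),
                                       np.asarray(train_y), grid, spec.seed)
            hp.setdefault("C", c)
            hp.setdefault("gamma", g)
    return replace(spec, hyperparams=hp)


def _build_estimator(spec: ClassifierSpec):
    hp = spec.hyperparams
    if spec.kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp["n_estimators"], max_features=hp["max_features"],
            random_state=spec.seed, n_jobs=1)
    if spec.kind == "svm_rbf":
        return SVC(kernel="rbf", C=hp["C"], gamma=hp["gamma"],
                   probability=True, random_state=spec.seed)
    return AdaBoostClassifier(
        estimator=DecisionTreeClassifier(random_state=spec.seed),
        n_estimators=hp["n_estimators"], random_state=spec.seed)


def train_and_predict(spec: ClassifierSpec, train_X: np.ndarray, train_y: np.ndarray,
                      apply_X: np.ndarray, n_classes: int | None = None) -> ClassifierOutput:
    """Fit one base classifier and return labels + probabilities on the apply set.

    SVM features are min–max scaled (fitted on the training rows); tree
    ensembles see raw features (scale-invariant).  Classes absent from the
    training set but present in the dictionary of size ``n_classes`` get
    zero probability.  Reproducible given ``spec.seed``.
    """
    train_X = np.asarray(train_X, float)
    apply_X = np.asarray(apply_X, float)
    train_y = np.asarray(train_y)
    if train_X.shape[1] != apply_X.shape[1]:
        raise ValueError("train/apply feature dimensions differ")
    if len(np.unique(train_y)) < 2:
        raise ValueError("single-class training set")
    if n_classes is None:
        n_classes = int(train_y.max())

    if spec.kind == "svm_rbf":
        train_X, apply_X, _ = normalize_features(train_X, apply_X)
    spec = resolve_hyperparams(spec, train_X.shape[1], train_X, train_y)
    est = _build_estimator(spec)
    est.fit(train_X, train_y)
    raw = est.predict_proba(apply_X)

    proba = np.zeros((apply_X.shape[0], n_classes))
    for j, cls in enumerate(est.classes_):
        proba[:, int(cls) - 1] = raw[:, j]
    rowsum = proba.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    proba /= rowsum
    labels = np.argmax(proba, axis=1) + 1  # argmax ties -> lowest class index
    return ClassifierOutput(labels=labels, proba=proba)
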