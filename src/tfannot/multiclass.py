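"""Multiclass strategies for superclass prediction.

Two strategies are provided on top of a pluggable family of binary base
learners (SVM with RBF or linear kernel, k-nearest neighbours, naive Bayes,
decision tree, random forest):

* one-versus-rest — one binary model per class, per-class decision scores
  usable for ROC analysis;
* the exhaustive error-correcting output code (ECOC) metaclassifier — for k
  classes, 2^(k-1) - 1 binary classifiers whose columns enumerate all
  non-degenerate bipartitions; prediction concatenates the binary outcomes
  into a bit string decoded by minimum Hamming distance to the class
  codewords, ties sharing probability equally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.multiclass import OneVsRestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

#: class order of the published five-class exhaustive code (first row is the
#: all-ones codeword)
TABLE_CLASS_ORDER = (
    "Other",
    "Basic domain",
    "Zinc finger",
    "Helix-turn-helix",
    "Beta scaffold",
)

BASE_LEARNERS = ("svm", "svm_linear", "knn", "nb", "tree", "rf")

#: hyperparameter grids for inner-CV tuning, keyed by learner spec
DEFAULT_GRIDS = {
    "svm": {"svc__C": [0.1, 1.0, 10.0, 100.0],
            "svc__gamma": [1e-3, 1e-2, 1e-1, 1.0]},
    "svm_linear": {"svc__C": [0.1, 1.0, 10.0, 100.0]},
    "knn": {"kneighborsclassifier__n_neighbors": [1, 3, 5, 7]},
    "nb": {},
    "tree": {"max_depth": [None, 5, 10]},
    "rf": {"n_estimators": [100, 500]},
}


def make_base_learner(spec: str = "svm", seed: int = 42):
    """Instantiate a binary base learner by name.

    SVMs and KNN are wrapped with feature standardization (their grids in
    :data:`DEFAULT_GRIDS` use pipeline parameter names accordingly).
    """
    if spec == "svm":
        return make_pipeline(StandardScaler(),
                             SVC(kernel="rbf", random_state=seed))
    if spec == "svm_linear":
        return make_pipeline(StandardScaler(),
                             SVC(kernel="linear", random_state=seed))
    if spec == "knn":
        return make_pipeline(StandardScaler(), KNeighborsClassifier())
    if spec == "nb":
        return GaussianNB()
    if spec == "tree":
        return DecisionTreeClassifier(random_state=seed)
    if spec == "rf":
        return RandomForestClassifier(random_state=seed)
    raise ValueError(f"unknown base learner {spec!r}; "
                     f"choose from {BASE_LEARNERS}")


@dataclass
class CodeMatrix:
    """Error-correcting output code: one row per class, one column per
    binary classifier."""

    classes: tuple
    code: np.ndarray  # k x L binary

    @property
    def n_classifiers(self) -> int:
        return self.code.shape[1]

    def row(self, cls: str) -> np.ndarray:
        return self.code[self.classes.index(cls)]

    def min_hamming_distance(self) -> int:
        k = len(self.classes)
        dists = [int(np.sum(self.code[i] != self.code[j]))
                 for i in range(k) for j in range(i + 1, k)]
        return min(dists)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            header = ["Superclass"] + [str(j + 1)
                                       for j in range(self.n_classifiers)]
            fh.write("\t".join(header) + "\n")
            for cls, row in zip(self.classes, self.code):
                fh.write("\t".join([cls] + [str(int(b)) for b in row]) + "\n")


def exhaustive_code(classes: Sequence[str]) -> CodeMatrix:
    """Dietterich's exhaustive code for k classes: 2^(k-1) - 1 columns.

    The first class's codeword is all ones; for the remaining classes, the
    columns enumerate the binary representations of 0 .. 2^(k-1) - 2 read
    most-significant bit first.  For five classes this reproduces the
    published 5 x 15 code column for column.
    """
    k = len(classes)
    if not 2 <= k <= 10:
        raise ValueError("exhaustive codes supported for 2..10 classes")
    n_cols = 2 ** (k - 1) - 1
    code = np.ones((k, n_cols), dtype=int)
    for j in range(n_cols):
        for i in range(1, k):
            code[i, j] = (j >> (k - 1 - i)) & 1
    return CodeMatrix(classes=tuple(classes), code=code)


def ecoc_decode(bits: Sequence[int], code: CodeMatrix) -> dict:
    """Minimum-Hamming-distance decoding to class probabilities.

    Rows at minimum distance share probability 1/|argmin|; all other classes
    get 0.
    """
    bits = np.asarray(bits, dtype=int)
    if bits.shape != (code.n_classifiers,):
        raise ValueError(f"expected {code.n_classifiers} bits, "
                         f"got {bits.shape}")
    dists = np.sum(code.code != bits[None, :], axis=1)
    winners = np.flatnonzero(dists == dists.min())
    probs = {c: 0.0 for c in code.classes}
    for i in winners:
        probs[code.classes[i]] = 1.0 / len(winners)
    return probs


class ECOCClassifier(BaseEstimator, ClassifierMixin):
    """Exhaustive-code ECOC metaclassifier.

    One binary base learner is trained per code column (positives = samples
    of classes whose row bit is 1).  Prediction concatenates the binary
    outcomes into a bit string and decodes it by minimum Hamming distance,
    with ties resolved into equal probabilities.

    Parameters
    ----------
    class_order : row order of the code matrix; defaults to the published
        five-superclass order (first class gets the all-ones codeword).
        When None, sorted unique training labels are used.
    base : base learner spec (see :func:`make_base_learner`).
    random_state : seed passed to stochastic base learners.
    """

    def __init__(self, class_order=TABLE_CLASS_ORDER, base="svm",
                 random_state=42):
        self.class_order = class_order
        self.base = base
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        order = (tuple(self.class_order) if self.class_order is not None
                 else tuple(sorted(set(y))))
        unknown = set(y) - set(order)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} not in class order")
        self.code_ = exhaustive_code(order)
        self.classes_ = np.array(order)
        class_index = {c: i for i, c in enumerate(order)}
        row_of = np.array([class_index[label] for label in y])
        self.estimators_ = []
        prototype = make_base_learner(self.base, self.random_state)
        for j in range(self.code_.n_classifiers):
            y_bin = self.code_.code[row_of, j]
            if len(np.unique(y_bin)) < 2:
                raise ValueError(
                    f"code column {j + 1} induces a one-sided split on "
                    f"this data")
            est = clone(prototype)
            est.fit(X, y_bin)
            self.estimators_.append(est)
        return self

    def predict_bits(self, X) -> np.ndarray:
        check_is_fitted(self, "estimators_")
        X = np.asarray(X)
        return np.column_stack([est.predict(X) for est in self.estimators_])

    def predict_proba(self, X) -> np.ndarray:
        bits = self.predict_bits(X)
        out = np.empty((len(bits), len(self.classes_)))
        for i, row in enumerate(bits):
            probs = ecoc_decode(row, self.code_)
            out[i] = [probs[c] for c in self.classes_]
        return out

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


class OvRClassifier(BaseEstimator, ClassifierMixin):
    """One-versus-rest multiclass wrapper over the pluggable base learners.

    ``decision_scores`` exposes per-class scores for ROC analysis (decision
    function when available, positive-class probability otherwise).
    """

    def __init__(self, base="svm", random_state=42):
        self.base = base
        self.random_state = random_state

    def fit(self, X, y):
        y = np.asarray(y)
        counts = {c: int(np.sum(y == c)) for c in set(y)}
        small = {c: n for c, n in counts.items() if n < 2}
        if small:
            raise ValueError(f"classes with < 2 training examples: {small}")
        self.model_ = OneVsRestClassifier(
            make_base_learner(self.base, self.random_state))
        self.model_.fit(X, y)
        self.classes_ = self.model_.classes_
        return self

    def decision_scores(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        try:
            scores = self.model_.decision_function(X)
        except AttributeError:
            scores = self.model_.predict_proba(X)
        scores = np.asarray(scores)
        if scores.ndim == 1:  # binary case
            scores = np.column_stack([-scores, scores])
        return scores

    def predict_proba(self, X) -> np.ndarray:
        """Softmax over the per-class decision scores."""
        scores = self.decision_scores(X)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.model_.predict(X)


def train_ecoc(X, y, base: str = "svm", class_order=TABLE_CLASS_ORDER,
               random_state: int = 42) -> ECOCClassifier:
    """Functional wrapper: fit an :class:`ECOCClassifier`."""
    return ECOCClassifier(class_order=class_order, base=base,
                          random_state=random_state).fit(X, y)


def one_vs_rest(X, y, base: str = "svm",
                random_state: int = 42) -> OvRClassifier:
    """Functional wrapper: fit an :class:`OvRClassifier`."""
    return OvRClassifier(base=base, random_state=random_state).fit(X, y)


_MODEL_MAGIC = b"tfannot-model\x001\n"


def save_model(model, path) -> None:
    """Serialize a fitted model with a versioned header."""
    import pickle
    with open(path, "wb") as fh:
        fh.write(_MODEL_MAGIC)
        pickle.dump(model, fh)


def load_model(path):
    """Load a model written by :func:`save_model` (header checked)."""
    import pickle
    with open(path, "rb") as fh:
        magic = fh.read(len(_MODEL_MAGIC))
        if magic != _MODEL_MAGIC:
            raise ValueError(f"{path}: not a recognized model file "
                             f"(bad or missing version header)")
        return pickle.load(fh)
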