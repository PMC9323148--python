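"""Craniosynostosis classification from cranial shape coefficients.

Observations are rows of shape coefficients ``alpha`` extracted from
the cranium-only model.  Five classifiers are supported (RBF-kernel
one-vs-one SVM, LDA with shared covariance and class priors, Gaussian
naive Bayes, 5-NN with nearest-among-tied-classes tie-break, and a
default decision tree).  Cross-validation is mirror-aware: mirrored
observations augment the training folds only, and a mirrored twin is
never in the training set of the fold that tests its original.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "FeatureTable",
    "CVPlan",
    "ClassificationReport",
    "CLASSIFIER_NAMES",
    "make_classifier",
    "make_cv_plan",
    "train_predict",
    "cross_validate",
    "sweep_components",
    "compute_report",
]

CLASSIFIER_NAMES = ("svm", "lda", "nb", "knn", "bdt")


@dataclass
class FeatureTable:
    """Shape-coefficient features with mirror bookkeeping.

    ``mirror_of[i]`` is the row index of observation i's unmirrored
    original (or -1 if row i is itself an original).
    """

    alpha: np.ndarray  # (n_rows, k)
    labels: np.ndarray
    mirrored: np.ndarray
    mirror_of: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, float)
        self.labels = np.asarray(self.labels)
        self.mirrored = np.asarray(self.mirrored, bool)
        self.mirror_of = np.asarray(self.mirror_of, np.int64)
        n = len(self.alpha)
        if not (len(self.labels) == len(self.mirrored) == len(self.mirror_of) == n):
            raise ValueError("inconsistent row counts")
        if not np.isfinite(self.alpha).all():
            raise ValueError("features contain non-finite values")

    @property
    def original_ids(self) -> np.ndarray:
        return np.flatnonzero(~self.mirrored)

    @classmethod
    def from_alphas(cls, alpha, labels, mirrored=None, mirror_of=None) -> "FeatureTable":
        alpha = np.asarray(alpha, float)
        n = len(alpha)
        if mirrored is None:
            mirrored = np.zeros(n, bool)
        if mirror_of is None:
            mirror_of = np.full(n, -1, np.int64)
        return cls(alpha, np.asarray(labels), np.asarray(mirrored, bool), np.asarray(mirror_of, np.int64))


@dataclass
class CVPlan:
    """Stratified folds over the unmirrored observations; training rows
    include the mirrors of training originals only."""

    test_folds: list = field(default_factory=list)   # list of int arrays
    train_folds: list = field(default_factory=list)  # list of int arrays

    def check_no_leakage(self, table: FeatureTable) -> None:
        """Assert the mirror-exclusion and partition invariants."""
        originals = set(table.original_ids.tolist())
        seen: set[int] = set()
        for test, train in zip(self.test_folds, self.train_folds):
            test_set = set(map(int, test))
            if test_set & seen:
                raise AssertionError("test folds overlap")
            seen |= test_set
            train_set = set(map(int, train))
            if test_set & train_set:
                raise AssertionError("test rows leak into training")
            # mirrors of test rows must be absent from training
            mirrors_of_test = {
                int(i) for i in range(len(table.mirror_of))
                if table.mirror_of[i] >= 0 and int(table.mirror_of[i]) in test_set
            }
            if mirrors_of_test & train_set:
                raise AssertionError("mirror of a test observation found in training fold")
        if seen != originals:
            raise AssertionError("test folds do not partition the unmirrored observations")


def make_cv_plan(table: FeatureTable, n_folds: int = 10, seed: int = 0) -> CVPlan:
    """Mirror-aware stratified k-fold plan (deterministic per seed)."""
    orig = table.original_ids
    labels = table.labels[orig]
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    k = n_folds
    if counts.min() < n_folds:
        k = max(2, int(counts.min()))
        import warnings

        warnings.warn(f"smallest class has {counts.min()} members; using {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    plan = CVPlan()
    mirrors_by_orig: dict[int, list[int]] = {}
    for i, orig_of in enumerate(table.mirror_of):
        if orig_of >= 0:
            mirrors_by_orig.setdefault(int(orig_of), []).append(i)
    for train_loc, test_loc in skf.split(np.zeros(len(orig)), labels):
        test_ids = orig[test_loc]
        train_ids = list(orig[train_loc])
        for oid in orig[train_loc]:
            train_ids.extend(mirrors_by_orig.get(int(oid), []))
        plan.test_folds.append(np.asarray(test_ids, np.int64))
        plan.train_folds.append(np.asarray(sorted(train_ids), np.int64))
    plan.check_no_leakage(table)
    return plan


class _TieBreakKNN:
    """5-NN, Euclidean; ties broken by the nearest neighbour among the
    tied classes (scikit-learn's default breaks ties by class order)."""

    def __init__(self, k: int = 5):
        self.k = k
        self._knn = KNeighborsClassifier(n_neighbors=k, metric="euclidean")

    def fit(self, X, y):
        y = np.asarray(y)
        self._knn.fit(X, y)
        self._y = y
        return self

    def predict(self, X):
        dist, idx = self._knn.kneighbors(X, n_neighbors=self.k)
        out = []
        for d_row, i_row in zip(dist, idx):
            votes = self._y[i_row]
            classes, counts = np.unique(votes, return_counts=True)
            winners = classes[counts == counts.max()]
            if len(winners) == 1:
                out.append(winners[0])
            else:
                # nearest neighbour whose class is among the tied classes
                tied = set(winners.tolist())
                for d, i in sorted(zip(d_row, i_row)):
                    if self._y[i] in tied:
                        out.append(self._y[i])
                        break
        return np.asarray(out)


def make_classifier(name: str, seed: int = 0):
    """Instantiate one of the five supported classifiers."""
    if name == "svm":
        return SVC(kernel="rbf", decision_function_shape="ovo", random_state=seed)
    if name == "lda":
        return LinearDiscriminantAnalysis()
    if name == "nb":
        return GaussianNB()
    if name == "knn":
        return _TieBreakKNN(5)
    if name == "bdt":
        return DecisionTreeClassifier(random_state=seed)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}")


def train_predict(name: str, train: FeatureTable, test: FeatureTable, seed: int = 0) -> np.ndarray:
    """Fit the named classifier on `train` and predict labels for `test`."""
    if len(train.alpha) == 0:
        raise ValueError("empty training set")
    if train.alpha.shape[1] != test.alpha.shape[1]:
        raise ValueError("train/test feature dimension mismatch")
    clf = make_classifier(name, seed=seed)
    clf.fit(train.alpha, train.labels)
    return np.asarray(clf.predict(test.alpha))


def _subset(table: FeatureTable, ids: np.ndarray, k: int) -> FeatureTable:
    return FeatureTable(
        table.alpha[ids, :k], table.labels[ids], table.mirrored[ids], table.mirror_of[ids]
    )


def cross_validate(
    table: FeatureTable, plan: CVPlan, classifier: str, n_components: int, seed: int = 0
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Pooled mirror-aware CV.  Returns (confusion matrix DataFrame,
    true labels, predicted labels); each original tested exactly once."""
    plan.check_no_leakage(table)
    classes = np.unique(table.labels)
    y_true, y_pred = [], []
    for test_ids, train_ids in zip(plan.test_folds, plan.train_folds):
        pred = train_predict(
            classifier, _subset(table, train_ids, n_components), _subset(table, test_ids, n_components), seed=seed
        )
        y_true.extend(table.labels[test_ids])
        y_pred.extend(pred)
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    C = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, pr in zip(y_true, y_pred):
        C.loc[t, pr] += 1
    return C, y_true, y_pred


def sweep_components(
    table: FeatureTable, plan: CVPlan, classifier: str, k_max: int = 100, seed: int = 0
) -> tuple[np.ndarray, int]:
    """Pooled CV accuracy for k = 1..k_max coefficients.

    Returns (accuracy array, chosen k = argmax, smallest k on ties)."""
    k_max = min(k_max, table.alpha.shape[1])
    accs = np.empty(k_max)
    for k in range(1, k_max + 1):
        C, y_true, y_pred = cross_validate(table, plan, classifier, k, seed=seed)
        accs[k - 1] = float((y_true == y_pred).mean())
    chosen = int(np.argmax(accs)) + 1  # argmax returns first (smallest) maximum
    return accs, chosen


@dataclass
class ClassificationReport:
    """Confusion matrix with the derived per-class metrics."""

    confusion: pd.DataFrame
    sensitivity: dict
    specificity: dict
    g_mean: float
    accuracy: float
    classifier: str | None = None
    n_components: int | None = None

    def summary(self) -> str:
        classes = list(self.confusion.index)
        w = max(6, max(len(str(c)) for c in classes) + 1)
        lines = ["Classification report", "=" * (w * (len(classes) + 1) + 24)]
        header = f"{'true/pred':<{w + 3}}" + "".join(f"{c:>{w}}" for c in classes)
        lines.append(header + f"{'sens':>8}{'spec':>8}")
        for c in classes:
            row = f"{c:<{w + 3}}" + "".join(f"{int(self.confusion.loc[c, d]):>{w}}" for d in classes)
            sens = self.sensitivity[c]
            spec = self.specificity[c]
            sens_s = f"{sens:.3f}" if sens == sens else "nan"
            lines.append(row + f"{sens_s:>8}{spec:>8.3f}")
        lines.append(f"g-mean          {self.g_mean:.3f}")
        lines.append(f"total accuracy  {self.accuracy:.3f}")
        if self.classifier:
            lines.append(f"classifier      {self.classifier} (k={self.n_components})")
        return "\n".join(lines)


def compute_report(
    confusion, class_names=None, classifier: str | None = None, n_components: int | None = None
) -> ClassificationReport:
    """Metrics from a square confusion matrix of counts (rows = true).

    sensitivity_c = C[c,c] / row_sum_c; specificity_c = TN_c / (TN_c +
    FP_c) one-vs-rest; g-mean = geometric mean of per-class
    sensitivities; accuracy = trace / total.
    """
    if isinstance(confusion, pd.DataFrame):
        C = confusion.to_numpy()
        names = list(confusion.index) if class_names is None else list(class_names)
    else:
        C = np.asarray(confusion)
        names = [f"class{i}" for i in range(len(C))] if class_names is None else list(class_names)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (C < 0).any() or not np.allclose(C, np.round(C)):
        raise ValueError("confusion matrix must hold nonnegative integer counts")
    C = np.round(C).astype(np.int64)
    total = C.sum()
    sens, spec = {}, {}
    sens_vals = []
    for i, name in enumerate(names):
        row = C[i].sum()
        if row == 0:
            import warnings

            warnings.warn(f"class {name!r} has no true samples; sensitivity undefined")
            sens[name] = float("nan")
        else:
            sens[name] = C[i, i] / row
            sens_vals.append(sens[name])
        fp = C[:, i].sum() - C[i, i]
        tn = total - row - fp
        spec[name] = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    g_mean = float(np.prod(sens_vals) ** (1.0 / len(sens_vals))) if sens_vals else float("nan")
    acc = float(np.trace(C) / total) if total else float("nan")
    return ClassificationReport(
        confusion=pd.DataFrame(C, index=names, columns=names),
        sensitivity=sens,
        specificity=spec,
        g_mean=g_mean,
        accuracy=acc,
        classifier=classifier,
        n_components=n_components,
    )
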