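"""Stop/move classifier benchmark: seven models, 10-fold CV, Eq-style metrics.

The benchmark compares logistic regression, Gaussian naive Bayes,
k-nearest neighbors (k = √n of the training set, made odd) and four
support-vector machines (linear C=1000; cubic polynomial C=1; RBF
C=1000, γ=0.01; sigmoid C=1) on the 45-dimensional feature windows.
Accuracy, precision, recall and F1 are computed from the TP/TN/FP/FN
counts with the move state (label 1) as the positive class, and each
model is summarized by a row-normalized 2×2 confusion matrix whose
diagonal is the per-class accuracy.

Features are z-standardized inside each training fold for the scale-
sensitive models (LR, KNN, SVM); Gaussian NB is fitted on raw features.
The kernel coefficient written as the library default for the cubic and
sigmoid kernels is pinned to 1 / (n_features × Var(X)) and recorded in
the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from roachloop.imu_features import FEATURE_COLUMNS

__all__ = [
    "ClassifierSpec",
    "ClassifierReport",
    "default_specs",
    "FAMILY_ORDER",
    "knn_default_k",
    "build_estimator",
    "train_classifier",
    "TrainedModel",
    "cross_validate",
    "evaluate_metrics",
    "confusion_matrix_normalized",
    "select_best",
]

#: Fixed presentation / tie-break order of the seven benchmark models.
FAMILY_ORDER = ["lr", "gaussian_nb", "knn", "svm_linear", "svm_cubic",
                "svm_rbf", "svm_sigmoid"]


@dataclass(frozen=True)
class ClassifierSpec:
    """One benchmark entry; unused fields are None for a family."""

    name: str
    family: str                      # {lr, gaussian_nb, knn, svm}
    kernel: str | None = None        # SVM only
    C: float | None = None
    gamma: float | str | None = None
    degree: int | None = None
    k_neighbors: int | None = None   # None -> sqrt(n_train) rule
    minkowski_p: int = 2
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.C is not None and self.C <= 0:
            raise ValueError("C must be positive")
        if isinstance(self.gamma, (int, float)) and self.gamma <= 0:
            raise ValueError("numeric gamma must be positive")
        if self.k_neighbors is not None and self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def default_specs() -> dict[str, ClassifierSpec]:
    """The seven benchmarked classifiers with their stated hyperparameters."""
    return {
        "lr": ClassifierSpec(name="lr", family="lr"),
        "gaussian_nb": ClassifierSpec(name="gaussian_nb", family="gaussian_nb",
                                      standardize=False),
        "knn": ClassifierSpec(name="knn", family="knn"),
        "svm_linear": ClassifierSpec(name="svm_linear", family="svm",
                                     kernel="linear", C=1000.0),
        "svm_cubic": ClassifierSpec(name="svm_cubic", family="svm",
                                    kernel="poly", degree=3, C=1.0,
                                    gamma="scale"),
        "svm_rbf": ClassifierSpec(name="svm_rbf", family="svm", kernel="rbf",
                                  C=1000.0, gamma=0.01),
        "svm_sigmoid": ClassifierSpec(name="svm_sigmoid", family="svm",
                                      kernel="sigmoid", C=1.0, gamma="scale"),
    }


def knn_default_k(n_train: int) -> int:
    """round(√n), incremented to odd to avoid binary voting ties."""
    if n_train < 1:
        raise ValueError("n_train must be >= 1")
    k = int(round(np.sqrt(n_train)))
    k = max(k, 1)
    if k % 2 == 0:
        k += 1
    return min(k, n_train)


def build_estimator(spec: ClassifierSpec, n_train: int):
    """Scikit-learn pipeline realizing one ClassifierSpec."""
    if spec.family == "lr":
        clf = LogisticRegression(max_iter=2000)
    elif spec.family == "gaussian_nb":
        clf = GaussianNB()
    elif spec.family == "knn":
        k = spec.k_neighbors or knn_default_k(n_train)
        clf = KNeighborsClassifier(n_neighbors=k, metric="minkowski",
                                   p=spec.minkowski_p)
    elif spec.family == "svm":
        clf = SVC(kernel=spec.kernel, C=spec.C,
                  gamma=spec.gamma if spec.gamma is not None else "scale",
                  degree=spec.degree or 3)
    else:
        raise ValueError(f"unknown family {spec.family!r}")
    if spec.standardize:
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])
    return Pipeline([("clf", clf)])


def _split_xy(table: pd.DataFrame):
    cols = [c for c in FEATURE_COLUMNS if c in table.columns]
    if len(cols) != len(FEATURE_COLUMNS):
        missing = set(FEATURE_COLUMNS) - set(cols)
        raise ValueError(f"feature table is missing columns: {sorted(missing)}")
    X = table[cols].to_numpy(float)
    y = table["label"].to_numpy(int)
    return X, y


@dataclass
class TrainedModel:
    """Fitted pipeline plus provenance used by the closed-loop stage."""

    pipeline: Pipeline
    spec: ClassifierSpec
    training_animals: tuple[str, ...]
    n_train: int

    def predict(self, X) -> np.ndarray:
        return self.pipeline.predict(np.asarray(X, float))


def train_classifier(table: pd.DataFrame, spec: ClassifierSpec,
                     seed: int = 0) -> TrainedModel:
    """Fit one spec on a full feature table (deterministic given inputs)."""
    X, y = _split_xy(table)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training table holds a single class; need both "
                         "stop and move windows")
    est = build_estimator(spec, n_train=len(y))
    est.fit(X, y)
    animals = tuple(sorted(set(table.get("animal_id", pd.Series([""])).astype(str))))
    return TrainedModel(pipeline=est, spec=spec, training_animals=animals,
                        n_train=len(y))


def evaluate_metrics(tp: int, tn: int, fp: int, fn: int
                     ) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, F1) from counts; 0/0 ratios are 0."""
    for v in (tp, tn, fp, fn):
        if v < 0:
            raise ValueError("counts must be non-negative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("no evaluated windows")
    accuracy = (tp + tn) / total
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return accuracy, precision, recall, f1


def confusion_matrix_normalized(truth, predicted) -> np.ndarray:
    """2×2 matrix of per-true-class rates; rows (true 0, true 1) sum to 1."""
    truth = np.asarray(truth, int)
    predicted = np.asarray(predicted, int)
    if truth.size == 0:
        raise ValueError("empty input")
    if truth.shape != predicted.shape:
        raise ValueError("truth and prediction lengths differ")
    mat = np.zeros((2, 2))
    for t, p in zip(truth, predicted):
        mat[t, p] += 1
    sums = mat.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return mat / sums


@dataclass
class ClassifierReport:
    """Cross-validation summary of one spec."""

    spec: ClassifierSpec
    seed: int
    k_folds: int
    fold_metrics: pd.DataFrame          # accuracy/precision/recall/f1 per fold
    confusion: np.ndarray               # row-normalized, pooled over folds
    counts: tuple[int, int, int, int]   # pooled TP, TN, FP, FN
    resolved_params: dict = field(default_factory=dict)

    @property
    def mean_metrics(self) -> pd.Series:
        return self.fold_metrics.mean()

    @property
    def per_class_accuracy(self) -> tuple[float, float]:
        """(stop, move) accuracy — the diagonal of the confusion matrix."""
        return float(self.confusion[0, 0]), float(self.confusion[1, 1])

    def to_dict(self) -> dict:
        return {
            "spec": {k: v for k, v in self.spec.__dict__.items()},
            "seed": self.seed,
            "k_folds": self.k_folds,
            "mean": self.mean_metrics.to_dict(),
            "per_fold": self.fold_metrics.to_dict(orient="list"),
            "confusion": self.confusion.tolist(),
            "counts": dict(zip(("TP", "TN", "FP", "FN"), self.counts)),
            "resolved_params": self.resolved_params,
        }


def cross_validate(table: pd.DataFrame, spec: ClassifierSpec,
                   k_folds: int = 10, seed: int = 42) -> ClassifierReport:
    """Shuffled k-fold cross-validation of one spec.

    Standardization (where used) is fitted on the training folds only.
    The confusion matrix pools the held-out predictions of all folds
    before row normalization.
    """
    X, y = _split_xy(table)
    for cls in (0, 1):
        if (y == cls).sum() < k_folds:
            raise ValueError(
                f"class {cls} has only {(y == cls).sum()} rows; "
                f"need at least {k_folds} for {k_folds}-fold CV")
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    rows = []
    tp = tn = fp = fn = 0
    all_truth: list[np.ndarray] = []
    all_pred: list[np.ndarray] = []
    resolved: dict = {}
    for train_idx, test_idx in kf.split(X):
        est = build_estimator(spec, n_train=len(train_idx))
        est.fit(X[train_idx], y[train_idx])
        pred = est.predict(X[test_idx])
        truth = y[test_idx]
        ftp = int(((pred == 1) & (truth == 1)).sum())
        ftn = int(((pred == 0) & (truth == 0)).sum())
        ffp = int(((pred == 1) & (truth == 0)).sum())
        ffn = int(((pred == 0) & (truth == 1)).sum())
        rows.append(evaluate_metrics(ftp, ftn, ffp, ffn))
        tp, tn, fp, fn = tp + ftp, tn + ftn, fp + ffp, fn + ffn
        all_truth.append(truth)
        all_pred.append(pred)
        if not resolved:
            clf = est.named_steps["clf"]
            if hasattr(clf, "_gamma"):
                resolved["gamma"] = float(clf._gamma)
            if hasattr(clf, "n_neighbors"):
                resolved["k_neighbors"] = int(clf.n_neighbors)
    fold_metrics = pd.DataFrame(rows, columns=["accuracy", "precision",
                                               "recall", "f1"])
    confusion = confusion_matrix_normalized(np.concatenate(all_truth),
                                            np.concatenate(all_pred))
    return ClassifierReport(spec=spec, seed=seed, k_folds=k_folds,
                            fold_metrics=fold_metrics, confusion=confusion,
                            counts=(tp, tn, fp, fn),
                            resolved_params=resolved)


def select_best(reports: list[ClassifierReport]) -> ClassifierSpec:
    """Winning spec: highest mean F1, ties by accuracy, then family order."""
    if not reports:
        raise ValueError("no reports to select from")

    def rank(r: ClassifierReport):
        m = r.mean_metrics
        order = (FAMILY_ORDER.index(r.spec.name)
                 if r.spec.name in FAMILY_ORDER else len(FAMILY_ORDER))
        return (-m["f1"], -m["accuracy"], order)

    return min(reports, key=rank).spec
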