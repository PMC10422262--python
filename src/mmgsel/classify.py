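"""SVM-RBF classifier contract and confusion-matrix utilities.

The wrapper selector scores feature subsets with a soft-margin support
vector machine using the radial basis kernel
K(x, x') = exp(-gamma ||x - x'||^2); multi-class problems use one-vs-one
voting.  The classifier itself is scikit-learn's SVC — this module pins the
contract (hyperparameters, determinism, label handling) the selector relies
on and the row-normalized percent confusion matrices used for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

#: Soft-margin penalty; no nested hyperparameter search is run inside the
#: wrapper, so one sensible default is fixed here.
DEFAULT_C = 10.0
#: Data-driven kernel width 1 / (n_features * Var[X]), scikit-learn's "scale".
DEFAULT_GAMMA = "scale"


@dataclass
class ConfusionMatrix:
    """Row-normalized percent confusion matrix with a fixed class order."""

    percent: np.ndarray
    classes: list

    @property
    def per_class_rates(self) -> np.ndarray:
        """Diagonal: percent of each true class predicted correctly."""
        return np.diag(self.percent)


def train(X: np.ndarray, y: np.ndarray, C: float = DEFAULT_C, gamma=DEFAULT_GAMMA) -> SVC:
    """Train a one-vs-one soft-margin RBF SVM.

    Raises
    ------
    ValueError
        On single-class input or non-finite rows.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.isfinite(X).all():
        raise ValueError("training matrix contains non-finite values")
    if len(np.unique(y)) < 2:
        raise ValueError("training needs at least 2 classes")
    model = SVC(C=C, gamma=gamma, kernel="rbf", decision_function_shape="ovo")
    model.fit(X, y)
    return model


def predict(model: SVC, X: np.ndarray) -> np.ndarray:
    """Predict one label per row; raises on feature-count mismatch."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"feature count {X.shape[1]} != training count {model.n_features_in_}"
        )
    return model.predict(X)


def confusion_percent(y_true, y_pred, class_order) -> ConfusionMatrix:
    """Percent confusion matrix: entry (i, j) = 100 P(pred = j | true = i).

    Every class in ``class_order`` must occur in ``y_true``, otherwise its
    row would be 0/0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    classes = list(class_order)
    counts = np.zeros((len(classes), len(classes)))
    index = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    if np.any(row_sums == 0):
        missing = [c for c, s in zip(classes, row_sums[:, 0]) if s == 0]
        raise ValueError(f"true classes absent from y_true: {missing}")
    return ConfusionMatrix(percent=100.0 * counts / row_sums, classes=classes)
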