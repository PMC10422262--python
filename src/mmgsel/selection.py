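"""Wrapper feature selection driven by CSA/GOA metaheuristics.

A continuous optimizer position (one coordinate per feature, searched in
[0, 1]) is decoded into a binary selection mask: each coordinate passes
through a transfer function mapping it to [0, 1] and is compared with a
threshold T — strictly larger means the feature is retained.  A candidate
mask is scored by the fitness

    Fitness = alpha * acc + (1 - alpha) * (1 - R / N),   alpha = 0.99,

where acc is the stratified K-fold cross-validated SVM-RBF accuracy on the
masked feature columns, R the number of selected features and N the total —
accuracy dominates, with a small parsimony reward for dropping features.
Features are z-scored inside each fold using training-fold statistics only,
so no information leaks from held-out data.

With the S1 sigmoid and positions confined to [0, 1], transformed values
span [0.5, 0.731]: thresholds up to 0.45 select every feature while the
0.5-0.6 range makes selection progressively sparser, which is what the
threshold-sweep experiment probes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.preprocessing import StandardScaler

from . import classify
from .features import FeatureMatrix
from .optimizers import OptimizerConfig, optimize

#: Transfer functions mapping an optimizer coordinate to [0, 1].  The
#: V-family takes absolute values since tanh(x) and x/sqrt(1+x^2) are
#: negative for x < 0 while T lies in (0, 1).
TRANSFER_FUNCTIONS = {
    "S1": lambda x: 1.0 / (1.0 + np.exp(-x)),
    "S2": lambda x: 1.0 / (1.0 + np.exp(-2.0 * x)),
    "S3": lambda x: 1.0 / (1.0 + np.exp(-x / 2.0)),
    "V1": lambda x: np.abs(np.tanh(x)),
    "V2": lambda x: np.abs(x / np.sqrt(1.0 + x**2)),
}


def transfer(name: str, x):
    """Apply transfer function ``name`` (S1, S2, S3, V1 or V2)."""
    try:
        fn = TRANSFER_FUNCTIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown transfer function {name!r}; expected one of "
            f"{sorted(TRANSFER_FUNCTIONS)}"
        ) from None
    out = fn(np.asarray(x, dtype=float))
    return float(out) if out.ndim == 0 else out


@dataclass
class SelectionMask:
    """Binary mask over feature columns; at least one bit is always set."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.sum() < 1:
            raise ValueError("mask must select at least one feature")

    @property
    def R(self) -> int:
        return int(self.bits.sum())


@dataclass
class CVConfig:
    """Cross-validation settings for mask evaluation.

    ``mode='kfold'`` uses one fixed stratified K-fold partition (seeded), so
    every fitness evaluation within a selection run sees the same folds and
    mask comparisons are consistent.  ``mode='holdout'`` uses a single
    stratified split — a cheaper option for large wrapper runs.
    """

    n_folds: int = 10
    seed: int = 0
    mode: str = "kfold"
    holdout_frac: float = 0.25
    C: float = classify.DEFAULT_C
    gamma: object = classify.DEFAULT_GAMMA


@dataclass
class MaskEvaluation:
    mean_acc: float
    fold_accs: np.ndarray
    confusion: classify.ConfusionMatrix
    per_class_rates: np.ndarray


@dataclass
class SelectionReport:
    """Best mask found by a selection run, with its cross-validated metrics."""

    mask: SelectionMask
    fitness: float
    fold_accs: np.ndarray
    mean_acc: float
    mean_R: float
    confusion: classify.ConfusionMatrix
    per_class_rates: np.ndarray
    threshold: float
    transfer_name: str
    algorithm: str
    seed: int
    fitness_history: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    @property
    def selected_features(self) -> list[str]:
        return [n for n, b in zip(self.feature_names, self.mask.bits) if b]

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "transfer": self.transfer_name,
            "threshold": self.threshold,
            "seed": self.seed,
            "fitness": self.fitness,
            "mean_acc": self.mean_acc,
            "mean_R": self.mean_R,
            "fold_accs": self.fold_accs.tolist(),
            "mask": self.mask.bits.astype(int).tolist(),
            "selected_features": self.selected_features,
            "per_class_rates": self.per_class_rates.tolist(),
            "confusion_percent": self.confusion.percent.tolist(),
            "confusion_classes": [str(c) for c in self.confusion.classes],
            "fitness_history": self.fitness_history.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def binarize(position: np.ndarray, tf_name: str, T: float) -> SelectionMask:
    """Decode a continuous position into a mask: bit = transfer(x) > T.

    If no coordinate clears the threshold, the single feature with the
    largest transformed value is kept (an empty feature set cannot be
    classified and the fitness is undefined at R = 0).
    """
    if not (0 < T < 1):
        raise ValueError("threshold T must lie in (0, 1)")
    values = transfer(tf_name, np.asarray(position, dtype=float))
    bits = values > T
    if not bits.any():
        bits = np.zeros_like(bits)
        bits[int(np.argmax(values))] = True
    return SelectionMask(bits=bits)


def fitness(acc: float, R: int, N: int, alpha: float = 0.99) -> float:
    """Selection fitness alpha * acc + (1 - alpha)(1 - R/N)."""
    if not (1 <= R <= N):
        raise ValueError("need 1 <= R <= N")
    if not (0.0 <= acc <= 1.0):
        raise ValueError("accuracy must lie in [0, 1]")
    return alpha * acc + (1.0 - alpha) * (1.0 - R / N)


def _splits(y: np.ndarray, cv: CVConfig):
    classes, counts = np.unique(y, return_counts=True)
    if cv.mode == "holdout":
        splitter = StratifiedShuffleSplit(
            n_splits=1, test_size=cv.holdout_frac, random_state=cv.seed
        )
    else:
        k = cv.n_folds
        if counts.min() < k:
            raise ValueError(
                f"class {classes[np.argmin(counts)]!r} has {counts.min()} members, "
                f"fewer than K={k} folds; use K <= {counts.min()}"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=cv.seed)
    return list(splitter.split(np.zeros(len(y)), y))


def evaluate_mask(
    mask: SelectionMask, fm: FeatureMatrix, cv: CVConfig | None = None
) -> MaskEvaluation:
    """Cross-validated SVM-RBF accuracy of the masked feature columns.

    Per fold: z-score with training-fold statistics, train on the masked
    training rows, score the held-out rows.  The confusion matrix pools
    held-out predictions over all folds and is row-normalized to percent.
    """
    cv = cv or CVConfig()
    X = fm.X[:, mask.bits]
    y = fm.y
    classes = list(np.unique(y))
    accs, y_true_all, y_pred_all = [], [], []
    for train_idx, test_idx in _splits(y, cv):
        scaler = StandardScaler().fit(X[train_idx])
        model = classify.train(
            scaler.transform(X[train_idx]), y[train_idx], C=cv.C, gamma=cv.gamma
        )
        pred = classify.predict(model, scaler.transform(X[test_idx]))
        accs.append(float(np.mean(pred == y[test_idx])))
        y_true_all.append(y[test_idx])
        y_pred_all.append(pred)
    fold_accs = np.asarray(accs)
    confusion = classify.confusion_percent(
        np.concatenate(y_true_all), np.concatenate(y_pred_all), classes
    )
    return MaskEvaluation(
        mean_acc=float(fold_accs.mean()),
        fold_accs=fold_accs,
        confusion=confusion,
        per_class_rates=confusion.per_class_rates,
    )


def mean_metrics(per_fold: list[tuple[float, int]]) -> tuple[float, float]:
    """Arithmetic means of per-fold (accuracy, selected-feature count)."""
    if not per_fold:
        raise ValueError("empty fold list")
    accs = [a for a, _ in per_fold]
    rs = [r for _, r in per_fold]
    return float(np.mean(accs)), float(np.mean(rs))


def select_features(
    fm: FeatureMatrix,
    algorithm: str = "csa",
    T: float = 0.5,
    tf_name: str = "S1",
    opt_cfg: OptimizerConfig | None = None,
    cv: CVConfig | None = None,
    alpha: float = 0.99,
) -> SelectionReport:
    """Run the wrapper: optimize masks by cross-validated fitness.

    The optimizer searches the [0, 1]^N box; each candidate position is
    decoded by ``binarize`` and scored with the fitness above.  The fold
    partition is fixed for the whole run, and identical masks are evaluated
    once (cached) since continuous positions frequently decode to the same
    mask.  The returned report re-evaluates the best mask with the same
    folds and carries the full confusion matrix; the fold-wise selected
    count is constant per mask, so ``mean_R`` equals R.
    """
    n = fm.n_features
    if opt_cfg is None:
        opt_cfg = OptimizerConfig(dim=n)
    if opt_cfg.dim != n:
        raise ValueError("opt_cfg.dim must equal the number of features")
    cv = cv or CVConfig(seed=opt_cfg.seed)

    cache: dict[bytes, float] = {}

    def objective(position: np.ndarray) -> float:
        mask = binarize(position, tf_name, T)
        key = np.packbits(mask.bits).tobytes()
        acc = cache.get(key)
        if acc is None:
            acc = evaluate_mask(mask, fm, cv).mean_acc
            cache[key] = acc
        return fitness(acc, mask.R, n, alpha)

    result = optimize(objective, algorithm, opt_cfg)
    best_mask = binarize(result.best_position, tf_name, T)
    ev = evaluate_mask(best_mask, fm, cv)
    return SelectionReport(
        mask=best_mask,
        fitness=result.best_fitness,
        fold_accs=ev.fold_accs,
        mean_acc=ev.mean_acc,
        mean_R=float(best_mask.R),
        confusion=ev.confusion,
        per_class_rates=ev.per_class_rates,
        threshold=T,
        transfer_name=tf_name,
        algorithm=algorithm,
        seed=opt_cfg.seed,
        fitness_history=result.fitness_history,
        feature_names=list(fm.names),
    )
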