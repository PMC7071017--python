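"""Classifier layer: classical models, class rebalancing, ensembles, metrics.

The same seven classifier families are applied to both the 21-feature
representation and the SDTW distance-space mapping: random forests, RBF and
linear SVMs, gradient boosting, k-nearest neighbors, naive Bayes, and a
boosted-decision-tree stand-in for C5.0.  Hyperparameters are chosen by
grid search under 10-fold cross-validation.

Ensembles combine the feature-based random forest and the shape-based RBF
SVM: a weighted average with weights derived from logistic-regression
coefficients, w_i = |c_i| / (|c_RF| + |c_SVM|), and stacking, where a top
layer model is fit on out-of-fold probability predictions of the bottom
models.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ConfusionMatrix",
    "EnsembleWeights",
    "train_classifier",
    "rebalance",
    "ensemble_weights",
    "weighted_average_predict",
    "stacking",
    "confusion_metrics",
    "confusion_from_predictions",
    "load_confusion_tables",
]


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for v in (self.tp, self.fp, self.tn, self.fn):
            if v < 0:
                raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EnsembleWeights:
    w_rf: float
    w_svm: float
    c_rf: float
    c_svm: float


_GRIDS = {
    "rf": (RandomForestClassifier, {"n_estimators": [100, 400], "min_samples_leaf": [1]}),
    "svm_rbf": (SVC, {"C": [1.0, 10.0, 100.0, 1000.0],
                      "gamma": ["scale", 0.1, 0.01, 0.001]}),
    "svm_linear": (SVC, {"C": [0.1, 1.0], "kernel": ["linear"]}),
    "gbm": (GradientBoostingClassifier, {"n_estimators": [100], "learning_rate": [0.1]}),
    "knn": (KNeighborsClassifier, {"n_neighbors": [1, 5, 7]}),
    "nb": (GaussianNB, {}),
    "c50": (AdaBoostClassifier, {"n_estimators": [50]}),
}


def _make_estimator(algo: str, seed: int):
    if algo not in _GRIDS:
        raise ValueError(f"unknown classifier {algo!r}; choose from {sorted(_GRIDS)}")
    cls, grid = _GRIDS[algo]
    kwargs = {}
    if algo in ("rf", "gbm"):
        kwargs["random_state"] = seed
    elif algo == "c50":
        kwargs = {"estimator": DecisionTreeClassifier(max_depth=3), "random_state": seed}
    elif algo in ("svm_rbf", "svm_linear"):
        kwargs = {"probability": True, "random_state": seed}
    est = cls(**kwargs)
    return est, grid


def train_classifier(X, y, algo: str = "rf", cv_folds: int = 10, seed: int = 0,
                     scale: bool = True):
    """Fit a named classifier with grid search under k-fold CV.

    Features are standardized inside the pipeline (distance- and
    margin-based models need it; tree models are indifferent).  Returns the
    fitted search object; ``.best_params_`` holds the chosen grid point.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    est, grid = _make_estimator(algo, seed)
    steps = ([("scale", StandardScaler())] if scale else []) + [("clf", est)]
    pipe = Pipeline(steps)
    grid = {f"clf__{k}": v for k, v in grid.items()}
    folds = min(cv_folds, int(np.bincount(y).min()))
    cv = StratifiedKFold(n_splits=max(folds, 2), shuffle=True, random_state=seed)
    search = GridSearchCV(pipe, grid, cv=cv, n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        search.fit(X, y)
    return search


def rebalance(X, y, mode: str = "undersample_balanced", seed: int = 0,
              negative_fraction: float = 0.7):
    """Produce a balanced training set.

    ``undersample_balanced``: keep ``negative_fraction`` of the negatives
    (sampled without replacement) and an equal count of positives — with
    1211 retained negatives this yields the 2422-instance balanced set.
    ``oversample_cnn``: resample the minority class with replacement up to
    parity (the caller regenerates windows at 75% overlap first).
    Returns ``(X_bal, y_bal, index)`` with ``index`` into the input rows.
    """
    X = np.asarray(X)
    y = np.asarray(y, dtype=int)
    neg = np.nonzero(y == 0)[0]
    pos = np.nonzero(y == 1)[0]
    if len(neg) == 0 or len(pos) == 0:
        raise ValueError("both classes must be present to rebalance")
    rng = np.random.default_rng(seed)
    if mode == "undersample_balanced":
        n_neg = int(round(negative_fraction * len(neg)))
        keep_neg = rng.choice(neg, size=n_neg, replace=False)
        n_pos = min(n_neg, len(pos))
        keep_pos = rng.choice(pos, size=n_pos, replace=False)
        idx = np.sort(np.concatenate([keep_neg, keep_pos]))
    elif mode == "oversample_cnn":
        minority, majority = (neg, pos) if len(neg) < len(pos) else (pos, neg)
        extra = rng.choice(minority, size=len(majority) - len(minority), replace=True)
        idx = np.sort(np.concatenate([majority, minority, extra]))
    else:
        raise ValueError(f"unknown rebalance mode {mode!r}")
    return X[idx], y[idx], idx


def ensemble_weights(c_rf: float, c_svm: float) -> EnsembleWeights:
    """Absolute-value-normalized weights from the two regression coefficients."""
    denom = abs(c_rf) + abs(c_svm)
    if denom == 0:
        raise ValueError("both coefficients are zero; weights undefined")
    return EnsembleWeights(w_rf=abs(c_rf) / denom, w_svm=abs(c_svm) / denom,
                           c_rf=c_rf, c_svm=c_svm)


def weighted_average_predict(p_rf, p_svm, weights: EnsembleWeights):
    """Convex blend p_e = w_RF·p_RF + w_SVM·p_SVM (threshold at 0.5)."""
    p_rf = np.asarray(p_rf, dtype=float)
    p_svm = np.asarray(p_svm, dtype=float)
    for p in (p_rf, p_svm):
        if np.any((p < 0) | (p > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
    return weights.w_rf * p_rf + weights.w_svm * p_svm


def stacking(bottom_preds: pd.DataFrame, labels, top_algo: str = "svm_rbf",
             seed: int = 0):
    """Fit a top-layer model on out-of-fold bottom-layer probabilities.

    ``bottom_preds`` must carry columns ``p_rf``, ``p_svm`` and ``fold``
    (the CV fold each prediction was held out from); the fold column is the
    evidence that predictions are out-of-fold, so its absence raises.
    """
    if "fold" not in bottom_preds.columns:
        raise ValueError("bottom predictions lack a 'fold' column: "
                         "out-of-fold predictions are required to avoid leakage")
    X = bottom_preds[["p_rf", "p_svm"]].to_numpy()
    return train_classifier(X, labels, algo=top_algo, seed=seed)


def confusion_from_predictions(y_true, y_pred) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def confusion_metrics(cm: ConfusionMatrix, decimals: int = 4):
    """(sensitivity, specificity, accuracy), rounded to report precision.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP);
    accuracy = (TP+TN)/total.  A zero denominator yields NaN for that
    metric rather than an exception.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    def _ratio(num, den):
        return round(num / den, decimals) if den > 0 else float("nan")

    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    acc = _ratio(cm.tp + cm.tn, cm.total)
    return sens, spec, acc


def load_confusion_tables() -> pd.DataFrame:
    """Published benchmark confusion rows (walking-recognition study tables).

    Columns: table, method, classifier, n_patterns, tp, fp, tn, fn,
    sensitivity, specificity, accuracy — the printed counts and metric
    cells, used as a worked-example regression fixture.
    """
    with importlib.resources.files("walkrec.data").joinpath(
            "confusion_tables.csv").open("r") as fh:
        return pd.read_csv(fh)
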