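"""End-to-end orchestration: records → windows → features/mapping → models.

Convenience layer used by the CLI, the acceptance script and the
integration tests.  The two classification routes share the windowing:

* feature route — 21 features per window, balanced training set, a
  classical classifier (random forest by default);
* shape route — prototype selection on the balanced training patterns
  (vertical projected acceleration), SDTW distance-space mapping, then a
  classifier (RBF SVM by default) on the mapped coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import elastic, features, models, prototypes
from .attitude import MadgwickConfig
from .imu_io import ImuSeries
from .preprocess import WindowLabel, build_processed, make_windows
from .synth import GaitParams, gen_record

__all__ = ["WindowSet", "windows_from_records", "synthetic_windows",
           "run_feature_route", "run_shape_route", "balanced_accuracy"]


@dataclass
class WindowSet:
    """Kept (non-discarded) windows with labels and handy per-window slices."""

    windows: list
    labels: np.ndarray          # 0/1 per kept window
    aez: np.ndarray             # (n, 250) vertical projected acceleration
    anorm: np.ndarray           # (n, 250) sensor-frame acceleration norm
    n_discarded: int = 0


def windows_from_records(records: list[ImuSeries], cfg: MadgwickConfig | None = None,
                         overlap: float = 0.5) -> WindowSet:
    """Process records through attitude + conditioning and cut labeled windows.

    The attitude filter is bootstrapped from the first accelerometer sample
    of each record (records start in an arbitrary orientation; bootstrapping
    removes the convergence transient from the first windows).
    """
    if cfg is None:
        cfg = MadgwickConfig(q_init="accel")
    kept, labels, n_disc = [], [], 0
    for rec in records:
        proc = build_processed(rec, cfg=cfg)
        for wdw in make_windows(proc, overlap=overlap):
            if wdw.label == WindowLabel.DISCARDED:
                n_disc += 1
                continue
            kept.append(wdw)
            labels.append(wdw.label.value)
    if not kept:
        raise ValueError("no usable windows: records too short or all impure")
    aez = np.stack([w.channel("aEz") for w in kept])
    anorm = np.stack([np.linalg.norm(w.values[:, 0:3], axis=1) for w in kept])
    return WindowSet(windows=kept, labels=np.asarray(labels, dtype=int),
                     aez=aez, anorm=anorm, n_discarded=n_disc)


def synthetic_windows(n_records: int = 60, seed: int = 0,
                      params: GaitParams | None = None,
                      overlap: float = 0.5) -> WindowSet:
    """Windows from a seeded collection of synthetic records."""
    params = params or GaitParams()
    records = [gen_record(seed=seed * 10007 + i, params=params) for i in range(n_records)]
    return windows_from_records(records, overlap=overlap)


def _split(n, test_fraction, rng):
    idx = rng.permutation(n)
    n_test = int(round(test_fraction * n))
    return idx[n_test:], idx[:n_test]


def run_feature_route(ws: WindowSet, algo: str = "rf", seed: int = 0,
                      test_fraction: float = 0.3, cv_folds: int = 10):
    """Train/evaluate the feature-based classifier on a window set.

    Returns ``(model, confusion_matrix, test_indices)``.
    """
    X, y, _ = features.feature_matrix(ws.windows)
    rng = np.random.default_rng(seed)
    tr, te = _split(len(y), test_fraction, rng)
    Xb, yb, _ = models.rebalance(X[tr], y[tr], seed=seed)
    model = models.train_classifier(Xb, yb, algo=algo, cv_folds=cv_folds, seed=seed)
    cm = models.confusion_from_predictions(y[te], model.predict(X[te]))
    return model, cm, te


def run_shape_route(ws: WindowSet, k: int = 10, method: str = "svm",
                    algo: str = "svm_rbf", seed: int = 0,
                    test_fraction: float = 0.3, cv_folds: int = 10,
                    max_prototype_pool: int = 300):
    """Train/evaluate the shape-based (mapped SDTW) classifier.

    Prototype selection runs on a subsample of the balanced training
    patterns capped at ``max_prototype_pool`` (the pairwise SDTW table is
    quadratic); the mapping and classification use all windows.
    Returns ``(model, confusion_matrix, prototype_set, test_indices)``.
    """
    y = ws.labels
    rng = np.random.default_rng(seed)
    tr, te = _split(len(y), test_fraction, rng)
    Xb, yb, idx_b = models.rebalance(ws.aez[tr], y[tr], seed=seed)
    if len(Xb) > max_prototype_pool:
        pick = rng.choice(len(Xb), size=max_prototype_pool, replace=False)
        pool, pool_y = Xb[pick], yb[pick]
    else:
        pool, pool_y = Xb, yb
    if method == "pam":
        proto = prototypes.pam_medoids(pool, k=k, labels=pool_y)
    elif method == "svm":
        proto = prototypes.select_support_vectors(pool, pool_y)
    elif method == "exhaustive":
        proto = prototypes.exhaustive_summary(pool, pool_y, k=k)
    elif method == "bfs":
        proto = prototypes.bfs_summary(pool, pool_y, k=k)
    elif method == "sa":
        proto = prototypes.sa_summary(pool, pool_y, k=k, seed=seed)
    else:
        raise ValueError(f"unknown prototype method {method!r}")
    mapped_train = elastic.map_many(Xb, proto)
    mapped_test = elastic.map_many(ws.aez[te], proto)
    model = models.train_classifier(mapped_train, yb, algo=algo,
                                    cv_folds=cv_folds, seed=seed)
    cm = models.confusion_from_predictions(y[te], model.predict(mapped_test))
    return model, cm, proto, te


def balanced_accuracy(cm: models.ConfusionMatrix) -> float:
    """Mean of sensitivity and specificity."""
    sens = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else float("nan")
    spec = cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp else float("nan")
    return 0.5 * (sens + spec)
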