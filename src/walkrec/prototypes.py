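"""Selection of representative query patterns S′ from a training set.

Three strategies summarize the training patterns TS (250-sample slices of
vertical projected acceleration) into a small set of 125-sample queries
used by the distance-space mapping:

* support vectors of a kernel SVM trained on the raw patterns under
  Euclidean geometry — the patterns on the class margin;
* PAM (partitioning around medoids) k-medoids under the subsequence-DTW
  distance — the most central real patterns, label-blind;
* supervised summarization — the k patterns maximizing the number of
  training items whose nearest prototype (best matching unit, BMU) shares
  their class, found exactly for tiny k or by breadth-first hill climbing /
  simulated annealing otherwise.

All three return *real* training patterns (never synthetic averages),
halved into queries.  The pairwise table ``dist[i, l]`` is the SDTW
distance using pattern i as the reference and the halved pattern l as the
query — note the asymmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np

from .elastic import halve_pattern, sdtw_many

__all__ = [
    "PrototypeSet",
    "sdtw_distance_table",
    "select_support_vectors",
    "pam_medoids",
    "summary_score",
    "exhaustive_summary",
    "bfs_summary",
    "sa_summary",
]


@dataclass
class PrototypeSet:
    """A set of 125-sample query patterns with provenance.

    queries: list of halved patterns; classes: label per query (inherited
    from the source pattern); source_ids: indices into TS; provenance: one
    of svm_sv, pam, supervised_exhaustive, supervised_bfs, supervised_sa.
    """

    queries: list
    source_ids: list[int]
    provenance: str
    classes: list[int] | None = None

    def __post_init__(self):
        if len(self.queries) < 1:
            raise ValueError("a prototype set needs at least one query")
        if len(set(self.source_ids)) != len(self.source_ids):
            raise ValueError("source_ids must be distinct")

    @property
    def k(self) -> int:
        return len(self.queries)


def _as_matrix(patterns) -> np.ndarray:
    return np.atleast_2d(np.asarray(patterns, dtype=float))


def sdtw_distance_table(patterns, half: str = "first") -> np.ndarray:
    """n×n table D[i, l] = d_SDTW(pattern_i as reference, halve(pattern_l)).

    Computed column-by-column with the batched DP (one query against all
    references at once).
    """
    X = _as_matrix(patterns)
    n = len(X)
    out = np.empty((n, n))
    for l in range(n):
        out[:, l] = sdtw_many(X, halve_pattern(X[l]))
    return out


def _subset(patterns, labels, ids, provenance, half="first") -> PrototypeSet:
    X = _as_matrix(patterns)
    ids = sorted(int(i) for i in ids)
    return PrototypeSet(
        queries=[halve_pattern(X[i], which=half) for i in ids],
        source_ids=ids,
        provenance=provenance,
        classes=None if labels is None else [int(labels[i]) for i in ids],
    )


# ---------------------------------------------------------------- SVM route

def select_support_vectors(patterns, labels, C: float = 1.0, gamma="scale",
                           half: str = "first") -> PrototypeSet:
    """S′ = the support vectors of an RBF SVM trained on the raw patterns."""
    from sklearn.svm import SVC

    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")
    svc = SVC(kernel="rbf", C=C, gamma=gamma)
    svc.fit(_as_matrix(patterns), labels)
    return _subset(patterns, labels, svc.support_, "svm_sv", half=half)


# ---------------------------------------------------------------- PAM route

def _assignment_cost(dist, medoids) -> float:
    # cost of assigning every pattern (reference axis) to its nearest medoid
    return float(dist[:, list(medoids)].min(axis=1).sum())


def pam_medoids(patterns, k: int, dist: np.ndarray | None = None,
                labels=None, half: str = "first") -> PrototypeSet:
    """Classic Kaufman–Rousseeuw PAM under the (asymmetric) SDTW table.

    Build phase greedily adds the pattern minimizing total assignment cost;
    Swap phase exchanges a medoid with a non-medoid while the cost strictly
    decreases.  Ties break toward the lowest pattern index.
    """
    X = _as_matrix(patterns)
    n = len(X)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if dist is None:
        dist = sdtw_distance_table(X, half=half)
    medoids: list[int] = []
    # Build
    for _ in range(k):
        best_c, best_j = np.inf, -1
        for j in range(n):
            if j in medoids:
                continue
            c = _assignment_cost(dist, medoids + [j])
            if c < best_c - 1e-12:
                best_c, best_j = c, j
        medoids.append(best_j)
    # Swap
    cost = _assignment_cost(dist, medoids)
    improved = True
    while improved:
        improved = False
        for mi, m in enumerate(sorted(medoids)):
            for j in range(n):
                if j in medoids:
                    continue
                trial = [x for x in medoids if x != m] + [j]
                c = _assignment_cost(dist, trial)
                if c < cost - 1e-12:
                    medoids, cost, improved = trial, c, True
                    break
            if improved:
                break
    return _subset(X, labels, medoids, "pam", half=half)


# --------------------------------------------------- supervised summarization

def summary_score(subset_ids, labels, dist) -> int:
    """F(S̃): training patterns whose BMU prototype shares their class.

    BMU ties break toward the lowest prototype index.
    """
    ids = sorted(int(i) for i in subset_ids)
    labels = np.asarray(labels, dtype=int)
    sub = dist[:, ids]
    bmu = np.argmin(sub, axis=1)  # argmin takes the first (lowest id) on ties
    proto_classes = labels[ids]
    return int(np.sum(proto_classes[bmu] == labels))


def exhaustive_summary(patterns, labels, k: int = 2, dist: np.ndarray | None = None,
                       half: str = "first", max_subsets: int = 10 ** 6) -> PrototypeSet:
    """Global maximizer of F over all C(n, k) subsets (tiny k only).

    Ties resolve to the lexicographically smallest id set; deterministic.
    """
    X = _as_matrix(patterns)
    n = len(X)
    if comb(n, k) > max_subsets:
        raise ValueError(
            f"C({n},{k}) = {comb(n, k)} subsets exceeds the enumeration guard; "
            "use bfs_summary or sa_summary"
        )
    if dist is None:
        dist = sdtw_distance_table(X, half=half)
    best_ids, best_f = None, -1
    for ids in combinations(range(n), k):  # lexicographic order; first win kept
        f = summary_score(ids, labels, dist)
        if f > best_f:
            best_ids, best_f = ids, f
    return _subset(X, labels, best_ids, "supervised_exhaustive", half=half)


def _swap_neighbors(ids, n):
    ids = set(ids)
    for out in sorted(ids):
        for inp in range(n):
            if inp not in ids:
                yield tuple(sorted((ids - {out}) | {inp}))


def bfs_summary(patterns, labels, k: int, dist: np.ndarray | None = None,
                init_ids=None, max_iters: int = 100, half: str = "first") -> PrototypeSet:
    """Breadth-first hill climbing over the one-swap neighborhood.

    Every neighbor of the current subset is scored per level and the best
    one kept; stops at a local optimum of F or after ``max_iters`` levels.
    Deterministic given the initial subset (default: the k lowest ids).
    """
    X = _as_matrix(patterns)
    n = len(X)
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}]")
    if dist is None:
        dist = sdtw_distance_table(X, half=half)
    cur = tuple(sorted(init_ids)) if init_ids is not None else tuple(range(k))
    cur_f = summary_score(cur, labels, dist)
    for _ in range(max_iters):
        best_nb, best_f = None, cur_f
        for nb in _swap_neighbors(cur, n):
            f = summary_score(nb, labels, dist)
            if f > best_f:
                best_nb, best_f = nb, f
        if best_nb is None:
            break
        cur, cur_f = best_nb, best_f
    return _subset(X, labels, cur, "supervised_bfs", half=half)


def sa_summary(patterns, labels, k: int, dist: np.ndarray | None = None,
               seed: int = 0, t_init: float | None = None, alpha: float = 0.95,
               proposals_per_temp: int | None = None, n_temps: int = 40,
               half: str = "first") -> PrototypeSet:
    """Simulated annealing over random one-swap proposals (maximizing F).

    Acceptance probability min(1, exp(ΔF / T)); geometric cooling T ← αT;
    the best state ever visited is returned.  All randomness flows from
    ``seed``.  The initial temperature defaults to one that accepts a
    unit-score drop ~80% of the time.
    """
    X = _as_matrix(patterns)
    n = len(X)
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}]")
    if dist is None:
        dist = sdtw_distance_table(X, half=half)
    rng = np.random.default_rng(seed)
    if t_init is None:
        t_init = -1.0 / np.log(0.8)  # P(accept ΔF = −1) ≈ 0.8
    if proposals_per_temp is None:
        proposals_per_temp = 50 * k
    cur = tuple(sorted(rng.choice(n, size=k, replace=False).tolist()))
    cur_f = summary_score(cur, labels, dist)
    best, best_f = cur, cur_f
    t = t_init
    for _ in range(n_temps):
        for _ in range(proposals_per_temp):
            out = cur[rng.integers(k)]
            candidates = [i for i in range(n) if i not in cur]
            if not candidates:
                break
            inp = candidates[rng.integers(len(candidates))]
            nb = tuple(sorted([i for i in cur if i != out] + [inp]))
            f = summary_score(nb, labels, dist)
            df = f - cur_f
            if df >= 0 or rng.random() < np.exp(df / t):
                cur, cur_f = nb, f
                if f > best_f:
                    best, best_f = nb, f
        t *= alpha
    return _subset(X, labels, best, "supervised_sa", half=half)
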