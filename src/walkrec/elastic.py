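"""Elastic sequence distances and the distance-space mapping.

Two distinct dynamic programs are provided:

* :func:`dtw_distance` — classic dynamic time warping with the symmetric
  step pattern and fixed (closed) endpoints; returns the accumulated cost
  P(π) along the optimal path together with the path itself.

* :func:`sdtw_distance` — subsequence (open-begin-end) DTW with the
  asymmetric step pattern: the short query z is matched against the best
  contiguous span x(a*:b*) of the long reference x.  Each query element is
  consumed exactly once (steps advance the query index by 1 and the
  reference index by 0, 1 or 2), so the accumulated cost is naturally
  normalized by the query length, giving a per-query-sample distance.

The shape-based classifier embeds a 250-sample window x into distance
space via φ_m(x) = (d_SDTW(x, z₁), …, d_SDTW(x, z_m)), where the z_i are
125-sample prototype queries (half a 250-sample training pattern —
slightly more than one step cycle at normal cadence).

The local cost is the absolute difference (patterns are scalar slices of
the vertical projected acceleration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Alignment",
    "dtw_distance",
    "sdtw_distance",
    "sdtw_many",
    "halve_pattern",
    "map_pattern",
    "map_many",
]

QUERY_LEN = 125
PATTERN_LEN = 250


@dataclass
class Alignment:
    """An optimal warping path: index pairs (into x, into y) and its cost."""

    pairs: list[tuple[int, int]]
    cost: float


def dtw_distance(x, y) -> tuple[float, Alignment]:
    """Full DTW under the symmetric step pattern with closed endpoints.

    Returns the accumulated optimal cost and its path.  The mean-per-step
    score used when comparing paths of different lengths is
    ``cost / len(path)``; the accumulated form is what is reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("DTW inputs must be non-empty")
    c = np.abs(x[:, None] - y[None, :])
    acc = np.full((n, m), np.inf)
    acc[0, 0] = c[0, 0]
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + c[0, j]
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + c[i, 0]
        for j in range(1, m):
            acc[i, j] = c[i, j] + min(acc[i - 1, j], acc[i, j - 1], acc[i - 1, j - 1])
    # traceback
    i, j = n - 1, m - 1
    pairs = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            choices = ((acc[i - 1, j - 1], i - 1, j - 1),
                       (acc[i - 1, j], i - 1, j),
                       (acc[i, j - 1], i, j - 1))
            _, i, j = min(choices, key=lambda t: t[0])
        pairs.append((i, j))
    pairs.reverse()
    return float(acc[-1, -1]), Alignment(pairs=pairs, cost=float(acc[-1, -1]))


def sdtw_distance(x, z) -> tuple[float, tuple[int, int]]:
    """Subsequence DTW of query ``z`` inside reference ``x``.

    Open begin and end on the reference; asymmetric steps (1,0), (1,1),
    (1,2) in (query, reference) indices.  Returns the per-query-sample
    distance and the matched span ``(a, b)`` in reference indices
    (inclusive, 0-based).
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    n, m = len(x), len(z)
    if m == 0 or n == 0:
        raise ValueError("SDTW inputs must be non-empty")
    if m > n:
        raise ValueError(f"query length {m} exceeds reference length {n}")
    # D[i, j]: cost of matching z[:i+1] ending at x[j]; start column tracked
    # for span recovery.
    c = np.abs(z[:, None] - x[None, :])
    d = np.full((m, n), np.inf)
    start = np.zeros((m, n), dtype=int)
    d[0] = c[0]
    start[0] = np.arange(n)
    for i in range(1, m):
        prev = d[i - 1]
        cand = np.full((3, n), np.inf)
        cand[0] = prev                      # (1, 0): repeat reference sample
        cand[1, 1:] = prev[:-1]             # (1, 1): advance by one
        cand[2, 2:] = prev[:-2]             # (1, 2): skip one reference sample
        best = np.argmin(cand, axis=0)
        d[i] = c[i] + cand[best, np.arange(n)]
        src = np.arange(n) - best
        src = np.clip(src, 0, n - 1)
        start[i] = start[i - 1][src]
    b = int(np.argmin(d[-1]))
    return float(d[-1, b] / m), (int(start[-1, b]), b)


def sdtw_many(X, z) -> np.ndarray:
    """Vectorized SDTW distances of one query against many references.

    ``X`` is (R, n); returns (R,) per-query-sample distances.  Same DP as
    :func:`sdtw_distance`, batched over the reference axis (spans are not
    tracked).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    z = np.asarray(z, dtype=float)
    r, n = X.shape
    m = len(z)
    if m > n:
        raise ValueError(f"query length {m} exceeds reference length {n}")
    d = np.abs(z[0] - X)
    for i in range(1, m):
        shift1 = np.full_like(d, np.inf)
        shift1[:, 1:] = d[:, :-1]
        shift2 = np.full_like(d, np.inf)
        shift2[:, 2:] = d[:, :-2]
        d = np.abs(z[i] - X) + np.minimum(d, np.minimum(shift1, shift2))
    return d.min(axis=1) / m


def halve_pattern(z, which: str = "first"):
    """Reduce a 250-sample training pattern to its 125-sample query half.

    The first half is the default; ``which="middle"`` takes the central
    125 samples instead.
    """
    z = np.asarray(z, dtype=float)
    if len(z) != PATTERN_LEN:
        raise ValueError(f"expected a {PATTERN_LEN}-sample pattern, got {len(z)}")
    if which == "first":
        return z[:QUERY_LEN]
    if which == "middle":
        off = (PATTERN_LEN - QUERY_LEN) // 2
        return z[off:off + QUERY_LEN]
    raise ValueError(f"unknown half selector {which!r}")


def map_pattern(x, prototypes) -> np.ndarray:
    """φ_m(x): SDTW distance of x to each prototype query, order preserved."""
    queries = getattr(prototypes, "queries", prototypes)
    if len(queries) == 0:
        raise ValueError("empty prototype set")
    return np.array([sdtw_distance(x, z)[0] for z in queries])


def map_many(X, prototypes) -> np.ndarray:
    """Mapped-feature matrix: row per reference window, column per prototype."""
    queries = getattr(prototypes, "queries", prototypes)
    if len(queries) == 0:
        raise ValueError("empty prototype set")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.stack([sdtw_many(X, z) for z in queries], axis=1)
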