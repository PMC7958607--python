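"""Independent brute-force oracles used to validate the fast implementations.

Each oracle works directly from the operation's definition (interval
enumeration, vertex enumeration, partition enumeration) and shares no code
with the implementation it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def choi_nonwear_oracle(
    counts: np.ndarray,
    window_min: int = 90,
    allowance_min: int = 2,
    stream_min: int = 30,
    epoch_seconds: int = 60,
) -> np.ndarray:
    """Mark non-wear as the union over ALL qualifying intervals [a, b).

    An interval qualifies iff it is long enough, starts and ends on zero
    epochs, contains at most the allowed number of nonzero epochs, and every
    nonzero run it touches has >= stream_min of zeros (or a series edge) on
    both sides. Enumerates anchors directly from this predicate.
    """
    counts = np.asarray(counts)
    n = counts.size
    w = int(round(window_min * 60 / epoch_seconds))
    allow = int(round(allowance_min * 60 / epoch_seconds))
    stream = int(round(stream_min * 60 / epoch_seconds))

    nz = (counts > 0).astype(int)
    # classify each nonzero epoch as belonging to an admissible run or not
    bad = np.zeros(n, dtype=int)
    i = 0
    while i < n:
        if counts[i] == 0:
            i += 1
            continue
        j = i
        while j < n and counts[j] != 0:
            j += 1
        # zero run before [i, j) and after
        k = i
        while k > 0 and counts[k - 1] == 0:
            k -= 1
        left_len = i - k
        left_ok = (k == 0 and left_len > 0) or left_len >= stream
        k = j
        while k < n and counts[k] == 0:
            k += 1
        right_len = k - j
        right_ok = (k == n and right_len > 0) or right_len >= stream
        if not (left_ok and right_ok):
            bad[i:j] = 1
        i = j

    nzp = np.concatenate(([0], np.cumsum(nz)))
    badp = np.concatenate(([0], np.cumsum(bad)))
    nonwear = np.zeros(n, dtype=bool)
    ends = np.arange(1, n + 1)
    zero_end = counts[ends - 1] == 0
    for a in range(n):
        if counts[a] != 0:
            continue
        ok = (
            (nzp[1:] - nzp[a] <= allow)
            & (badp[1:] - badp[a] == 0)
            & zero_end
            & (ends - a >= w)
        )
        # constraints are prefix-monotone: the largest valid end covers all
        valid = np.flatnonzero(ok[a:])
        if valid.size:
            b = a + valid[-1] + 1
            nonwear[a:b] = True
    return nonwear


def quantreg_vertex_oracle(y: np.ndarray, X: np.ndarray, tau: float = 0.5) -> float:
    """Minimum check loss by enumerating all exact fits through p points."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape

    def loss(beta):
        r = y - X @ beta
        return float(np.sum(r * (tau - (r < 0))))

    best = np.inf
    for idx in combinations(range(n), p):
        Xi = X[list(idx)]
        if abs(np.linalg.det(Xi)) < 1e-12:
            continue
        beta = np.linalg.solve(Xi, y[list(idx)])
        best = min(best, loss(beta))
    return best


def _set_partitions(items):
    if not items:
        yield []
        return
    head, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [head]] + part[i + 1 :]
        yield part + [[head]]


def kmeans_partition_oracle(X: np.ndarray, k: int) -> float:
    """Optimal within-cluster sum of squares over all partitions into <= k sets."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    best = np.inf
    for part in _set_partitions(list(range(n))):
        if len(part) > k:
            continue
        ss = 0.0
        for block in part:
            pts = X[block]
            ss += float(np.sum((pts - pts.mean(axis=0)) ** 2))
        best = min(best, ss)
    return best
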