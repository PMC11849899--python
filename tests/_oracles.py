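"""Independent first-principles oracles used by the test suite.

The naive agglomerator recomputes cluster-to-cluster distances from their
definitions (cross-pair extremes/means, recursive midpoint formulas, the
pairwise-sum centroid identity) at every step, with no Lance-Williams
in-place updates, so it exercises a fully independent code path.
"""

from __future__ import annotations

from itertools import product

import numpy as np


def _leaves(cluster) -> list[int]:
    if isinstance(cluster, int):
        return [cluster]
    out = []
    for child in cluster:
        out.extend(_leaves(child))
    return out


def _cross_pairs(a, b, delta):
    return [delta[i, j] for i, j in product(_leaves(a), _leaves(b))]


def _wpgma(a, b, delta, memo):
    key = (a, b)
    if key in memo:
        return memo[key]
    if isinstance(a, tuple):
        val = (_wpgma(a[0], b, delta, memo) + _wpgma(a[1], b, delta, memo)) / 2.0
    elif isinstance(b, tuple):
        val = (_wpgma(a, b[0], delta, memo) + _wpgma(a, b[1], delta, memo)) / 2.0
    else:
        val = delta[a, b]
    memo[key] = memo[(b, a)] = val
    return val


def _median_sq(a, b, delta2, memo):
    key = (a, b)
    if key in memo:
        return memo[key]
    if isinstance(a, tuple):
        val = (
            (_median_sq(a[0], b, delta2, memo) + _median_sq(a[1], b, delta2, memo)) / 2.0
            - _median_sq(a[0], a[1], delta2, memo) / 4.0
        )
    elif isinstance(b, tuple):
        val = (
            (_median_sq(a, b[0], delta2, memo) + _median_sq(a, b[1], delta2, memo)) / 2.0
            - _median_sq(b[0], b[1], delta2, memo) / 4.0
        )
    else:
        val = delta2[a, b]
    memo[key] = memo[(b, a)] = val
    return val


def _centroid_sq(a, b, delta2):
    """Squared centroid distance from pairwise squared distances:
    ||c_A - c_B||^2 = mean cross delta2 - W_A/|A|^2 - W_B/|B|^2."""
    la, lb = _leaves(a), _leaves(b)
    na, nb = len(la), len(lb)
    s_ab = sum(delta2[i, j] for i in la for j in lb)
    w_a = sum(delta2[i, j] for x, i in enumerate(la) for j in la[x + 1:])
    w_b = sum(delta2[i, j] for x, i in enumerate(lb) for j in lb[x + 1:])
    return s_ab / (na * nb) - w_a / na**2 - w_b / nb**2


def naive_agglomerate(values: np.ndarray, linkage: str):
    """Greedy agglomeration with per-step from-scratch cluster distances.

    Returns a list of (frozenset of merged leaves, height), heights on the
    input distance scale. Tie-break: smallest (i, j) over clusters in
    creation order.
    """
    delta = np.asarray(values, dtype=float)
    delta2 = delta**2
    squared = linkage in ("centroid", "median", "ward_d2")
    clusters: list = list(range(len(delta)))
    wpgma_memo: dict = {}
    median_memo: dict = {}

    def cdist(a, b) -> float:
        if linkage == "single":
            return min(_cross_pairs(a, b, delta))
        if linkage == "complete":
            return max(_cross_pairs(a, b, delta))
        if linkage == "average":
            return float(np.mean(_cross_pairs(a, b, delta)))
        if linkage == "mcquitty":
            return _wpgma(a, b, delta, wpgma_memo)
        if linkage == "centroid":
            return _centroid_sq(a, b, delta2)
        if linkage == "median":
            return _median_sq(a, b, delta2, median_memo)
        if linkage == "ward_d2":
            na, nb = len(_leaves(a)), len(_leaves(b))
            return 2.0 * na * nb / (na + nb) * _centroid_sq(a, b, delta2)
        raise ValueError(linkage)

    merges = []
    while len(clusters) > 1:
        best = (np.inf, -1, -1)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                v = cdist(clusters[i], clusters[j])
                if v < best[0]:
                    best = (v, i, j)
        v, i, j = best
        new = (clusters[i], clusters[j])
        height = float(np.sqrt(v)) if squared else float(v)
        merges.append((frozenset(_leaves(new)), height))
        clusters = [c for t, c in enumerate(clusters) if t not in (i, j)] + [new]
    return merges


def brute_force_hybrids(values: np.ndarray, groups, threshold: float) -> int:
    """Double-loop count of cross-group pairs at distance >= threshold."""
    n = len(groups)
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            if groups[i] != groups[j] and values[i, j] >= threshold:
                count += 1
    return count
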