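"""Hierarchical agglomerative clustering and cophenetic model selection.

Seven linkage rules are implemented through the Lance-Williams update:
single, complete, average (UPGMA), mcquitty (WPGMA), centroid, median and
ward_d2. The geometric rules (centroid, median, ward_d2) operate on squared
dissimilarities with a square-root back-transform, so reported merge heights
are always on the input distance scale. Ties at the minimal merge distance
are broken by the smallest (row, col) index pair, making trees deterministic.

The cophenetic correlation coefficient (CCC) — the Pearson correlation
between the input distances and the heights at which pairs first merge —
scores how faithfully each tree represents its distance matrix; the grid
over distance metrics x linkages selects the combination to use for
heterotic grouping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from heterogroup.distance import METRICS, DistanceMatrix, genetic_distance
from heterogroup.genotype_io import GenotypeMatrix

LINKAGES = ("single", "complete", "average", "mcquitty", "centroid", "median", "ward_d2")
_SQUARED_LINKAGES = ("centroid", "median", "ward_d2")


@dataclass
class MergeTree:
    """Agglomerative merge history.

    Nodes 0..n-1 are leaves; node n+t is the cluster created by merge t.
    ``merges`` lists (left, right, height) in merge order; heights are on the
    input distance scale. ``has_inversions`` flags non-monotone height
    sequences (possible under centroid/median linkage).
    """

    n_leaves: int
    labels: list[str]
    merges: list[tuple[int, int, float]]
    linkage: str = ""
    metric_name: str = ""
    has_inversions: bool = False

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError(
                f"{self.n_leaves} leaves require {self.n_leaves - 1} merges, "
                f"got {len(self.merges)}"
            )

    def leaves_under(self, node: int) -> list[int]:
        if node < self.n_leaves:
            return [node]
        left, right, _ = self.merges[node - self.n_leaves]
        return self.leaves_under(left) + self.leaves_under(right)


def _lance_williams(linkage: str, ni: int, nj: int, nk: int) -> tuple[float, float, float, float]:
    """Coefficients (alpha_i, alpha_j, beta, gamma) for d(i+j, k)."""
    if linkage == "single":
        return 0.5, 0.5, 0.0, -0.5
    if linkage == "complete":
        return 0.5, 0.5, 0.0, 0.5
    if linkage == "average":
        return ni / (ni + nj), nj / (ni + nj), 0.0, 0.0
    if linkage == "mcquitty":
        return 0.5, 0.5, 0.0, 0.0
    if linkage == "centroid":
        s = ni + nj
        return ni / s, nj / s, -(ni * nj) / (s * s), 0.0
    if linkage == "median":
        return 0.5, 0.5, -0.25, 0.0
    if linkage == "ward_d2":
        s = ni + nj + nk
        return (ni + nk) / s, (nj + nk) / s, -nk / s, 0.0
    raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")


def agglomerate(d: DistanceMatrix, linkage: str = "average") -> MergeTree:
    """Build an agglomerative tree from a distance matrix."""
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    n = d.n
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    if np.isnan(d.values).any():
        raise ValueError("distance matrix contains NaN")

    squared = linkage in _SQUARED_LINKAGES
    work = d.values.astype(float) ** 2 if squared else d.values.astype(float).copy()
    np.fill_diagonal(work, np.inf)
    active = list(range(n))  # cluster node ids, in creation order
    rowof = {node: idx for idx, node in enumerate(active)}  # node -> row in work
    sizes = {node: 1 for node in active}
    merges: list[tuple[int, int, float]] = []

    for t in range(n - 1):
        # minimal entry among active pairs; np.argmin's row-major first
        # occurrence implements the smallest-(row, col) tie-break
        rows = [rowof[node] for node in active]
        sub = work[np.ix_(rows, rows)]
        bi, bj = divmod(int(np.argmin(sub)), len(rows))
        if bi > bj:
            bi, bj = bj, bi
        best = sub[bi, bj]
        node_i, node_j = active[bi], active[bj]
        ri, rj = rowof[node_i], rowof[node_j]
        height = float(np.sqrt(best)) if squared else float(best)
        new_node = n + t
        merges.append((node_i, node_j, height))

        ni, nj = sizes[node_i], sizes[node_j]
        d_ij = work[ri, rj]
        for node_k in active:
            if node_k in (node_i, node_j):
                continue
            rk = rowof[node_k]
            ai, aj, beta, gamma = _lance_williams(linkage, ni, nj, sizes[node_k])
            new = (
                ai * work[ri, rk]
                + aj * work[rj, rk]
                + beta * d_ij
                + gamma * abs(work[ri, rk] - work[rj, rk])
            )
            work[ri, rk] = work[rk, ri] = new
        work[rj, :] = np.inf
        work[:, rj] = np.inf
        work[ri, ri] = np.inf

        active.remove(node_i)
        active.remove(node_j)
        active.append(new_node)
        rowof[new_node] = ri
        sizes[new_node] = ni + nj

    heights = [h for _, _, h in merges]
    inversions = any(b < a - 1e-12 for a, b in zip(heights, heights[1:]))
    return MergeTree(
        n_leaves=n,
        labels=list(d.labels),
        merges=merges,
        linkage=linkage,
        metric_name=d.metric_name,
        has_inversions=inversions,
    )


def cophenetic(t: MergeTree) -> DistanceMatrix:
    """Cophenetic distances: height of the lowest merge containing each pair."""
    n = t.n_leaves
    c = np.full((n, n), np.inf)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for idx, (left, right, height) in enumerate(t.merges):
        joined = members.pop(left) + members.pop(right)
        # lowest containing merge: with inversions an ancestor may sit lower
        block = np.ix_(joined, joined)
        c[block] = np.minimum(c[block], height)
        members[n + idx] = joined
    np.fill_diagonal(c, 0.0)
    return DistanceMatrix(labels=list(t.labels), values=c, metric_name="cophenetic")


def ccc(d: DistanceMatrix, c: DistanceMatrix) -> float:
    """Cophenetic correlation: Pearson r over the n(n-1)/2 off-diagonal pairs.

    Returns NaN (undefined) when either vector has zero variance.
    """
    if d.labels != c.labels:
        raise ValueError("distance and cophenetic matrices have different labels")
    x, y = d.condensed(), c.condensed()
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class CccGrid:
    """Cophenetic correlation per distance metric x linkage method."""

    metrics: list[str]
    linkages: list[str]
    values: np.ndarray  # metrics x linkages
    best_metric: str = field(init=False)
    best_linkage: str = field(init=False)

    def __post_init__(self) -> None:
        masked = np.where(np.isfinite(self.values), self.values, -np.inf)
        i, j = np.unravel_index(np.argmax(masked), self.values.shape)
        self.best_metric = self.metrics[i]
        self.best_linkage = self.linkages[j]

    @property
    def best_value(self) -> float:
        return float(self.values[self.metrics.index(self.best_metric),
                                 self.linkages.index(self.best_linkage)])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.metrics, columns=self.linkages)


def ccc_grid(
    g: GenotypeMatrix,
    metrics: list[str] | None = None,
    linkages: list[str] | None = None,
) -> CccGrid:
    """Compute the CCC for every distance metric x linkage combination."""
    metrics = list(METRICS) if metrics is None else list(metrics)
    linkages = list(LINKAGES) if linkages is None else list(linkages)
    vals = np.zeros((len(metrics), len(linkages)))
    for i, metric in enumerate(metrics):
        d = genetic_distance(g, metric)
        for j, linkage in enumerate(linkages):
            tree = agglomerate(d, linkage)
            vals[i, j] = ccc(d, cophenetic(tree))
    return CccGrid(metrics=metrics, linkages=linkages, values=vals)


def cut_tree(t: MergeTree, k: int) -> np.ndarray:
    """Cut into k groups by removing the k-1 last (highest) merges.

    Returns contiguous integer labels 1..k, numbered by first-leaf
    appearance in sample order.
    """
    n = t.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    parent = list(range(n + len(t.merges)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for idx, (left, right, _) in enumerate(t.merges[: n - k]):
        node = n + idx
        parent[find(left)] = node
        parent[find(right)] = node

    labels = np.zeros(n, dtype=int)
    seen: dict[int, int] = {}
    for leaf in range(n):
        root = find(leaf)
        if root not in seen:
            seen[root] = len(seen) + 1
        labels[leaf] = seen[root]
    return labels


def _newick_escape(name: str) -> str:
    if any(ch in name for ch in " \t()[]':;,"):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(t: MergeTree) -> str:
    """Serialize the tree to newick with branch lengths = height differences."""
    n = t.n_leaves
    height = {i: 0.0 for i in range(n)}
    for idx, (_, _, h) in enumerate(t.merges):
        height[n + idx] = h

    def render(node: int, parent_height: float) -> str:
        bl = parent_height - height[node]
        if node < n:
            return f"{_newick_escape(t.labels[node])}:{bl:.10g}"
        left, right, h = t.merges[node - n]
        return f"({render(left, h)},{render(right, h)}):{bl:.10g}"

    left, right, h = t.merges[-1]
    return f"({render(left, h)},{render(right, h)});"
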