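"""Heterotic group assignment, hybrid enumeration and pedigree cross-tabs.

A heterotic group is a set of inbred lines that combine well with lines of
other groups; hybrids between genetically distant groups are expected to
show the strongest heterosis. Groups are obtained by cutting the
agglomerative tree built from the selected distance x linkage combination,
and candidate hybrids are cross-group pairs whose genetic distance meets a
dissimilarity benchmark (default 0.35, inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from heterogroup.distance import DistanceMatrix, genetic_distance
from heterogroup.genotype_io import GenotypeMatrix
from heterogroup.hclust import agglomerate, cut_tree


@dataclass
class HeterotticAssignment:
    samples: list[str]
    groups: np.ndarray  # integer labels 1..k
    metric: str
    linkage: str
    summary: pd.DataFrame  # per-group size and distance summary

    def group_of(self) -> dict[str, int]:
        return dict(zip(self.samples, (int(x) for x in self.groups)))


def _group_summary(d: DistanceMatrix, groups: np.ndarray) -> pd.DataFrame:
    rows = []
    for gidx in np.unique(groups):
        idx = np.flatnonzero(groups == gidx)
        row: dict = {"group": int(gidx), "size": len(idx)}
        if len(idx) < 2:
            row.update(mean=np.nan, min=np.nan, max=np.nan,
                       min_pair=None, max_pair=None, singleton=True)
        else:
            sub = d.values[np.ix_(idx, idx)]
            iu = np.triu_indices(len(idx), k=1)
            vals = sub[iu]

            def pair(which: int) -> tuple[str, str]:
                a, b = iu[0][which], iu[1][which]
                return tuple(sorted((d.labels[idx[a]], d.labels[idx[b]])))

            lo_hits = np.flatnonzero(np.isclose(vals, vals.min()))
            hi_hits = np.flatnonzero(np.isclose(vals, vals.max()))
            row.update(
                mean=float(vals.mean()),
                min=float(vals.min()),
                max=float(vals.max()),
                min_pair=min(pair(h) for h in lo_hits),
                max_pair=min(pair(h) for h in hi_hits),
                singleton=False,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def assign_heterotic_groups(
    g: GenotypeMatrix,
    k: int = 3,
    metric: str = "ibs",
    linkage: str = "average",
    d: DistanceMatrix | None = None,
) -> HeterotticAssignment:
    """Cluster the panel and cut into k heterotic groups.

    Composes distance -> agglomerate -> cut_tree; pass a precomputed ``d``
    to skip the distance computation. Per-group size, mean/min/max distance
    and the extreme pairs are summarized.
    """
    if k < 2:
        raise ValueError("need k >= 2 heterotic groups")
    if d is None:
        d = genetic_distance(g, metric)
    tree = agglomerate(d, linkage)
    groups = cut_tree(tree, k)
    return HeterotticAssignment(
        samples=list(d.labels),
        groups=groups,
        metric=metric,
        linkage=linkage,
        summary=_group_summary(d, groups),
    )


def enumerate_hybrids(
    d: DistanceMatrix,
    groups: np.ndarray | list,
    threshold: float = 0.35,
) -> pd.DataFrame:
    """All cross-group pairs with distance >= threshold, most distant first.

    Returns columns parent_a, parent_b, group_a, group_b, distance; attrs
    carry per-group-pair counts. For [0,1]-bounded metrics a threshold
    outside [0,1] is rejected.
    """
    groups = np.asarray(groups)
    if len(groups) != d.n:
        raise ValueError("one group label per sample required")
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least two groups to enumerate hybrids")
    bounded = d.metric_name in ("ibs", "gower", "jaccard")
    if bounded and not 0.0 <= threshold <= 1.0:
        raise ValueError(
            f"threshold {threshold} outside [0, 1] for bounded metric {d.metric_name!r}"
        )
    iu = np.triu_indices(d.n, k=1)
    cross = groups[iu[0]] != groups[iu[1]]
    hit = cross & (d.values[iu] >= threshold)
    rows = []
    for a, b in zip(iu[0][hit], iu[1][hit]):
        ga, gb = groups[a], groups[b]
        if (gb, d.labels[b]) < (ga, d.labels[a]):
            a, b, ga, gb = b, a, gb, ga
        rows.append((d.labels[a], d.labels[b], ga, gb, d.values[min(a, b), max(a, b)]))
    out = pd.DataFrame(rows, columns=["parent_a", "parent_b", "group_a", "group_b", "distance"])
    out = out.sort_values(
        ["distance", "parent_a", "parent_b"], ascending=[False, True, True]
    ).reset_index(drop=True)
    pair_counts = (
        out.groupby(["group_a", "group_b"]).size().to_dict() if len(out) else {}
    )
    out.attrs["pair_counts"] = {f"{a}x{b}": int(c) for (a, b), c in pair_counts.items()}
    out.attrs["total"] = int(len(out))
    return out


def group_by_pedigree_crosstab(
    assignment: HeterotticAssignment,
    pedigree: dict[str, str] | list[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Heterotic group x source population contingency table.

    Returns (crosstab with counts, per-source modal-group coverage). Samples
    without a pedigree label fall in an ``unknown`` column. Row percentages
    are attached as attrs['row_pct'].
    """
    if isinstance(pedigree, dict):
        labels = [pedigree.get(s, "unknown") for s in assignment.samples]
    else:
        labels = list(pedigree)
        if len(labels) != len(assignment.samples):
            raise ValueError("one pedigree label per sample required")
    tab = pd.crosstab(
        pd.Series(assignment.groups, name="heterotic_group"),
        pd.Series(labels, name="source_population"),
    )
    row_pct = tab.div(tab.sum(axis=1), axis=0) * 100.0
    tab.attrs["row_pct"] = row_pct
    modal_rows = []
    for src in tab.columns:
        col = tab[src]
        modal = col.idxmax()
        modal_rows.append(
            {
                "source_population": src,
                "n": int(col.sum()),
                "modal_group": int(modal),
                "n_in_modal": int(col.max()),
                "coverage_pct": 100.0 * float(col.max()) / float(col.sum()),
            }
        )
    return tab, pd.DataFrame(modal_rows)
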