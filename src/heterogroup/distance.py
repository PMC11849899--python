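"""Genetic distance matrices between individuals.

Four dissimilarities are provided: identity-by-state (allele-sharing),
Gower, Euclidean, and Jaccard on alt-allele presence. All metrics use
pairwise-complete loci — a locus enters a pair's denominator only when both
individuals are called there — which keeps the matrices well-defined at the
~90% call rates typical of filtered SNP panels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from heterogroup.genotype_io import MISSING, GenotypeMatrix

METRICS = ("ibs", "gower", "euclidean", "jaccard")


@dataclass
class DistanceMatrix:
    """Labeled symmetric dissimilarity matrix with a zero diagonal."""

    labels: list[str]
    values: np.ndarray
    metric_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} labels")
        if not np.allclose(self.values, self.values.T, atol=1e-9, equal_nan=True):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal is not zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy's condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    def to_lower_triangle(self, path: str | Path, fmt: str = "%.6f") -> None:
        with open(path, "w") as fh:
            for i, lab in enumerate(self.labels):
                vals = "\t".join(fmt % v for v in self.values[i, :i])
                fh.write(lab + ("\t" + vals if vals else "") + "\n")


def _pairwise(g: GenotypeMatrix, numer_fn, denom_fn, metric_name: str) -> DistanceMatrix:
    """Generic pairwise-complete accumulation: d_ij = numer / denom per pair."""
    x = g.dosage_float()
    n = g.n_samples
    out = np.zeros((n, n))
    ok = ~np.isnan(x)
    for i in range(n):
        both = ok[i] & ok
        numer = numer_fn(x[i], x, both)
        denom = denom_fn(x[i], x, both)
        bad = denom == 0
        bad[i] = False
        if bad.any():
            j = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"samples {g.samples[i]!r} and {g.samples[j]!r} share no comparable marker"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            out[i] = numer / denom
    out[np.arange(n), np.arange(n)] = 0.0
    out = (out + out.T) / 2.0  # remove float asymmetry
    return DistanceMatrix(labels=list(g.samples), values=out, metric_name=metric_name)


def ibs_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """1 - proportion of alleles identical by state.

    Per locus the two individuals share 2 - |x_i - x_j| of their 2 compared
    alleles (dosage difference counts mismatching alleles of the unordered
    genotype pairs), so distance = sum |x_i - x_j| / (2 x #complete loci).
    """
    return _pairwise(
        g,
        lambda xi, x, both: np.where(both, np.abs(x - xi), 0.0).sum(axis=1),
        lambda xi, x, both: 2.0 * both.sum(axis=1),
        "ibs",
    )


def gower_distance(g: GenotypeMatrix, range_mode: str = "observed") -> DistanceMatrix:
    """Gower dissimilarity with dosages as numeric variables on [0, 2].

    Per locus k, similarity is 1 - |x_ik - x_jk| / range_k; zero-range loci
    contribute no term. ``range_mode='fixed'`` uses the theoretical range 2
    for every locus instead of the observed per-marker range.
    """
    if range_mode == "fixed":
        rng = np.full(g.n_markers, 2.0)
    elif range_mode == "observed":
        x = g.dosage_float()
        with np.errstate(invalid="ignore"):
            rng = np.nanmax(x, axis=0) - np.nanmin(x, axis=0)
    else:
        raise ValueError(f"range_mode must be 'observed' or 'fixed', got {range_mode!r}")
    usable = rng > 0

    def numer(xi, x, both):
        w = both & usable
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(w, np.abs(x - xi) / rng, 0.0).sum(axis=1)

    return _pairwise(g, numer, lambda xi, x, both: (both & usable).sum(axis=1), "gower")


def euclidean_distance(g: GenotypeMatrix, mean_scale: bool = False) -> DistanceMatrix:
    """Euclidean distance on dosage vectors over pairwise-complete loci.

    With ``mean_scale`` the squared sum is rescaled by (total markers /
    #complete markers) so pairs with different amounts of missingness are
    comparable.
    """
    x = g.dosage_float()
    n, m = x.shape
    ok = ~np.isnan(x)
    out = np.zeros((n, n))
    for i in range(n):
        both = ok[i] & ok
        cnt = both.sum(axis=1)
        bad = cnt == 0
        bad[i] = False
        if bad.any():
            j = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"samples {g.samples[i]!r} and {g.samples[j]!r} share no comparable marker"
            )
        sq = np.where(both, (x - x[i]) ** 2, 0.0).sum(axis=1)
        if mean_scale:
            with np.errstate(invalid="ignore", divide="ignore"):
                sq = sq / cnt * m
        out[i] = np.sqrt(sq)
    out[np.arange(n), np.arange(n)] = 0.0
    out = (out + out.T) / 2.0
    return DistanceMatrix(labels=list(g.samples), values=out, metric_name="euclidean")


def jaccard_distance(g: GenotypeMatrix, presence: str = "alt") -> DistanceMatrix:
    """Jaccard dissimilarity on per-locus allele presence.

    Each individual is binarized to presence of the alternate allele (dosage
    >= 1); ``presence='minor'`` binarizes to carriage of the panel-wise minor
    allele instead. Similarity = |intersection| / |union| over
    pairwise-complete loci; pairs with an empty union get distance 0.
    """
    x = g.dosage_float()
    if presence == "alt":
        pres = x >= 1
    elif presence == "minor":
        ok = ~np.isnan(x)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.nansum(x, axis=0) / (2.0 * ok.sum(axis=0))
        minor_is_alt = freq <= 0.5
        pres = np.where(minor_is_alt, x >= 1, x <= 1)
    else:
        raise ValueError(f"presence must be 'alt' or 'minor', got {presence!r}")
    pres = pres & ~np.isnan(x)
    ok = ~np.isnan(x)
    n = g.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        both = ok[i] & ok
        bad = both.sum(axis=1) == 0
        bad[i] = False
        if bad.any():
            j = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"samples {g.samples[i]!r} and {g.samples[j]!r} share no comparable marker"
            )
        inter = (pres[i] & pres & both).sum(axis=1)
        union = ((pres[i] | pres) & both).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = np.where(union > 0, inter / union, 1.0)
        out[i] = 1.0 - sim
    out[np.arange(n), np.arange(n)] = 0.0
    out = (out + out.T) / 2.0
    return DistanceMatrix(labels=list(g.samples), values=out, metric_name="jaccard")


def genetic_distance(g: GenotypeMatrix, metric: str, **kwargs) -> DistanceMatrix:
    """Dispatch to one of the four metrics by name."""
    fns = {
        "ibs": ibs_distance,
        "gower": gower_distance,
        "euclidean": euclidean_distance,
        "jaccard": jaccard_distance,
    }
    if metric not in fns:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    return fns[metric](g, **kwargs)


def summarize_distances(d: DistanceMatrix) -> dict:
    """Off-diagonal minimum/maximum pairs (with labels) and the mean.

    Ties at an extreme are broken by lexicographic label order of the pair.
    """
    if d.n < 2:
        raise ValueError("need at least two samples to summarize distances")
    iu = np.triu_indices(d.n, k=1)
    vals = d.values[iu]

    def extreme(best: float) -> tuple[str, str, float]:
        hits = np.flatnonzero(np.isclose(vals, best))
        pairs = sorted(
            tuple(sorted((d.labels[iu[0][h]], d.labels[iu[1][h]]))) for h in hits
        )
        a, b = pairs[0]
        return a, b, float(best)

    lo = extreme(vals.min())
    hi = extreme(vals.max())
    return {
        "min_pair": lo[:2],
        "min": lo[2],
        "max_pair": hi[:2],
        "max": hi[2],
        "mean": float(vals.mean()),
    }
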