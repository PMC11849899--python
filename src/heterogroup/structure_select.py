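"""Population structure: PCA, optimal-K selection, Evanno Delta-K, membership.

K selection offers three PCA-score-based routes (elbow on within-cluster sum
of squares, mean silhouette width, and the gap statistic with a uniform-box
reference) plus the Evanno second-difference statistic on an externally
supplied log-probability table (the shape produced by Bayesian admixture
software). Membership assignment applies the breeding-panel convention:
an individual joins the group holding >= threshold (default 80%) of its
ancestry, otherwise it is designated admixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from heterogroup.genotype_io import GenotypeMatrix

K_METHODS = ("elbow", "silhouette", "gap")


@dataclass
class PcaResult:
    scores: np.ndarray  # samples x components
    explained_variance_ratio: np.ndarray
    n_components: int
    labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.n_components)]
        return pd.DataFrame(self.scores, index=self.labels, columns=cols)


@dataclass
class KSelection:
    method: str
    k_values: list[int]
    scores: list[float]
    chosen_k: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"K": self.k_values, "score": self.scores})


def pca(g: GenotypeMatrix, n_components: int = 10, scale: bool = False) -> PcaResult:
    """PCA of the dosage matrix.

    Zero-variance markers are excluded and missing dosages mean-imputed per
    marker before centering (and optional unit scaling). Component signs
    follow a deterministic convention: the largest-magnitude loading of each
    component is made positive.
    """
    x = g.dosage_float()
    col_mean = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(col_mean, inds[1])
    var = x.var(axis=0)
    x = x[:, var > 0]
    if n_components > min(x.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples, n_informative_markers)"
            f"={min(x.shape)}"
        )
    if scale:
        x = (x - x.mean(axis=0)) / x.std(axis=0)
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    # deterministic sign: largest |loading| positive per component
    for c in range(n_components):
        load = model.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, c] *= -1.0
    return PcaResult(
        scores=scores,
        explained_variance_ratio=model.explained_variance_ratio_,
        n_components=n_components,
        labels=list(g.samples),
    )


def _wss(scores: np.ndarray, k: int, seed: int) -> tuple[float, np.ndarray]:
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(scores)
    return float(km.inertia_), km.labels_


def select_k(
    scores: PcaResult | np.ndarray,
    k_range: range | list[int] = range(1, 11),
    method: str = "silhouette",
    seed: int = 0,
    gap_b: int = 50,
) -> KSelection:
    """Choose the number of subpopulations from PCA scores.

    elbow: K at the maximal second difference of the within-cluster sum of
    squares (interior K only). silhouette: K maximizing mean silhouette
    width (K=1 skipped with a warning). gap: smallest K with
    gap(K) >= gap(K+1) - s(K+1), reference = uniform draws over the bounding
    box of the scores, B=``gap_b``.
    """
    x = scores.scores if isinstance(scores, PcaResult) else np.asarray(scores)
    ks = sorted(k_range)
    n = x.shape[0]
    if ks[0] < 1 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie within [1, {n - 1}]")
    if method not in K_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {K_METHODS}")

    if method == "elbow":
        wss = [_wss(x, k, seed)[0] for k in ks]
        if len(ks) < 3:
            raise ValueError("elbow needs at least 3 candidate K values")
        second = [wss[i - 1] - 2 * wss[i] + wss[i + 1] for i in range(1, len(ks) - 1)]
        chosen = ks[1 + int(np.argmax(second))]
        return KSelection("elbow", ks, wss, chosen)

    if method == "silhouette":
        if 1 in ks:
            warnings.warn("silhouette undefined at K=1; skipping it", stacklevel=2)
        use = [k for k in ks if k >= 2]
        sil = [silhouette_score(x, _wss(x, k, seed)[1]) for k in use]
        chosen = use[int(np.argmax(sil))]
        scores_out = [float("nan") if k == 1 else sil[use.index(k)] for k in ks]
        return KSelection("silhouette", ks, scores_out, chosen)

    # gap statistic (Tibshirani et al.), uniform-box reference
    rng = np.random.default_rng(seed)
    lo, hi = x.min(axis=0), x.max(axis=0)
    log_w = np.array([np.log(max(_wss(x, k, seed)[0], 1e-300)) for k in ks])
    ref = np.empty((gap_b, len(ks)))
    for b in range(gap_b):
        xb = rng.uniform(lo, hi, size=x.shape)
        ref[b] = [np.log(max(_wss(xb, k, seed)[0], 1e-300)) for k in ks]
    gap = ref.mean(axis=0) - log_w
    s = ref.std(axis=0) * np.sqrt(1.0 + 1.0 / gap_b)
    chosen = ks[-1]
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - s[i + 1]:
            chosen = ks[i]
            break
    return KSelection("gap", ks, list(gap), chosen)


def evanno_delta_k(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Evanno second-difference statistic from a (K, replicate, lnp) table.

    Delta-K(K) = |L(K+1) - 2 L(K) + L(K-1)| / sd(lnp at K), defined for
    interior K only; the optimum is the arg-max over defined values.
    Invariant to adding a constant to every lnp.
    """
    cols = {c.lower(): c for c in table.columns}
    kcol, lcol = cols.get("k"), cols.get("lnp", cols.get("lnpd"))
    if kcol is None or lcol is None:
        raise ValueError("table needs columns K and lnp")
    grouped = table.groupby(kcol)[lcol]
    ks = np.array(sorted(grouped.groups))
    if np.any(np.diff(ks) != 1):
        raise ValueError("K values must be contiguous")
    if len(ks) < 3:
        raise ValueError("Delta-K needs at least 3 consecutive K values")
    counts = grouped.count()
    if (counts < 2).any():
        raise ValueError("Delta-K needs >= 2 replicates per K")
    mean = grouped.mean().loc[ks].to_numpy()
    sd = grouped.std(ddof=1).loc[ks].to_numpy()
    delta = np.full(len(ks), np.nan)
    flagged = np.zeros(len(ks), dtype=bool)
    for i in range(1, len(ks) - 1):
        num = abs(mean[i + 1] - 2 * mean[i] + mean[i - 1])
        if sd[i] == 0:
            flagged[i] = True
        else:
            delta[i] = num / sd[i]
    out = pd.DataFrame({"K": ks, "mean_lnp": mean, "sd_lnp": sd,
                        "delta_k": delta, "sd_zero": flagged})
    if np.all(np.isnan(delta)):
        raise ValueError("Delta-K undefined everywhere (zero replicate variance)")
    optimal = int(ks[int(np.nanargmax(delta))])
    return out, optimal


def membership_from_partition(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Ancestry-like fractions from a hard K-partition of score space.

    Fraction of sample i in group k is proportional to
    exp(-0.5 (d_ik / sigma_k)^2), where d_ik is the distance from i to group
    k's centroid and sigma_k the mean centroid distance of the group's own
    members — a deterministic, self-contained stand-in for ancestry
    fractions produced by admixture software. Samples well inside a cluster
    approach fraction 1 for it; samples between clusters split their mass.
    """
    groups = np.unique(labels)
    cents = np.stack([scores[labels == gidx].mean(axis=0) for gidx in groups])
    dist = np.linalg.norm(scores[:, None, :] - cents[None, :, :], axis=2)
    sigma = np.array(
        [max(dist[labels == gidx, t].mean(), 1e-12) for t, gidx in enumerate(groups)]
    )
    z = -0.5 * (dist / sigma[None, :]) ** 2
    z -= z.max(axis=1, keepdims=True)
    q = np.exp(z)
    return q / q.sum(axis=1, keepdims=True)


def assign_membership(
    fractions: np.ndarray,
    threshold: float = 0.80,
    group_names: list[str] | None = None,
) -> pd.DataFrame:
    """Assign samples to groups by an ancestry-fraction threshold.

    A sample joins its arg-max group when the maximum fraction meets the
    threshold, otherwise it is labeled ``admixed``. The returned frame has
    attrs ``group_counts`` and ``admixed_fraction``.
    """
    q = np.asarray(fractions, dtype=float)
    if q.ndim != 2:
        raise ValueError("fractions must be a samples x K matrix")
    if not np.allclose(q.sum(axis=1), 1.0, atol=1e-3):
        raise ValueError("ancestry fractions must sum to 1 per sample")
    k = q.shape[1]
    if not (1.0 / k) < threshold <= 1.0:
        warnings.warn(
            f"threshold {threshold} outside (1/K, 1]: every sample will be assigned",
            stacklevel=2,
        )
    names = group_names or [f"group{i + 1}" for i in range(k)]
    arg = q.argmax(axis=1)
    top = q.max(axis=1)
    assigned = np.where(top >= threshold, np.array(names, dtype=object)[arg], "admixed")
    out = pd.DataFrame({"group": assigned, "max_fraction": top, "argmax_group":
                        np.array(names, dtype=object)[arg]})
    counts = out["group"].value_counts().to_dict()
    out.attrs["group_counts"] = {name: int(counts.get(name, 0)) for name in names}
    out.attrs["admixed_count"] = int(counts.get("admixed", 0))
    out.attrs["admixed_fraction"] = float(counts.get("admixed", 0)) / len(out)
    return out
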