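"""Distance-based analysis of molecular variance (AMOVA), PhiPT and gene flow.

The one-level AMOVA partitions squared inter-individual distances among and
within predefined groups. With squared distances delta^2:

    SS_total  = sum_{i<j} delta^2_ij / N
    SS_within = sum_g sum_{i<j in g} delta^2_ij / n_g
    SS_among  = SS_total - SS_within

Mean squares use df (k-1, N-k); the among-group variance component is
Va = (MS_among - MS_within) / n0 with n0 = (N - sum n_g^2 / N) / (k - 1),
and PhiPT = Va / (Va + Vw). Significance comes from permuting group labels.
Gene flow uses the haploid-style transform Nm = (1 - Phi) / (2 Phi).

The conventional input is squared Euclidean distance on dosage vectors
(the codominant-data convention of population-genetics spreadsheets); any
distance matrix may be supplied with ``squared`` declaring its scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from heterogroup.distance import DistanceMatrix
from heterogroup.genotype_io import GenotypeMatrix


@dataclass
class AmovaResult:
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    ms_among: float
    ms_within: float
    va: float  # among-group component, truncated at 0
    va_raw: float  # untruncated estimate
    vw: float
    n0: float
    phi_pt: float
    pct_among: float
    pct_within: float
    p_value: float | None = None
    n_permutations: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": ["Among groups", "Within groups", "Total"],
                "df": [self.df_among, self.df_within, self.df_among + self.df_within],
                "SS": [self.ss_among, self.ss_within, self.ss_among + self.ss_within],
                "MS": [self.ms_among, self.ms_within, np.nan],
                "est_var": [self.va, self.vw, self.va + self.vw],
                "pct": [self.pct_among, self.pct_within, 100.0],
                "phi_pt": [self.phi_pt, np.nan, np.nan],
                "p": [self.p_value, np.nan, np.nan],
            }
        )


def _phi_from_ss(
    sq: np.ndarray, codes: np.ndarray, k: int
) -> tuple[float, float, float, float, float, float, float, float]:
    """Return (ss_among, ss_within, ms_among, ms_within, n0, va_raw, phi,
    phi_raw). ``phi`` truncates a negative Va at 0; ``phi_raw`` does not and
    is the continuous statistic used for permutation comparisons."""
    n = len(codes)
    iu = np.triu_indices(n, k=1)
    ss_total = sq[iu].sum() / n
    ss_within = 0.0
    sizes = np.zeros(k)
    for gidx in range(k):
        idx = np.flatnonzero(codes == gidx)
        sizes[gidx] = len(idx)
        if len(idx) > 1:
            blk = sq[np.ix_(idx, idx)]
            ss_within += blk[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    df_among, df_within = k - 1, n - k
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within if df_within > 0 else np.nan
    n0 = (n - (sizes**2).sum() / n) / df_among
    va_raw = (ms_among - ms_within) / n0
    vw = ms_within
    va = max(va_raw, 0.0)
    denom = va + vw
    phi = va / denom if denom > 0 else np.nan
    denom_raw = va_raw + vw
    phi_raw = va_raw / denom_raw if denom_raw > 0 else np.nan
    return ss_among, ss_within, ms_among, ms_within, n0, va_raw, phi, phi_raw


def variance_components_from_ss(
    ss_among: float, ss_within: float, group_sizes: list[int] | np.ndarray
) -> AmovaResult:
    """AMOVA algebra from printed sums of squares and group sizes.

    Useful for recomputing published AMOVA tables whose raw distances are
    not available: df, MS, n0, Va, Vw, PhiPT and percent columns all follow
    from SS and the group sizes alone.
    """
    sizes = np.asarray(group_sizes, dtype=float)
    k = len(sizes)
    n = int(sizes.sum())
    df_among, df_within = k - 1, n - k
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    n0 = (n - (sizes**2).sum() / n) / df_among
    va_raw = (ms_among - ms_within) / n0
    va = max(va_raw, 0.0)
    vw = ms_within
    phi = va / (va + vw) if va + vw > 0 else np.nan
    return AmovaResult(
        df_among=df_among,
        df_within=df_within,
        ss_among=ss_among,
        ss_within=ss_within,
        ms_among=ms_among,
        ms_within=ms_within,
        va=va,
        va_raw=va_raw,
        vw=vw,
        n0=n0,
        phi_pt=phi,
        pct_among=100.0 * va / (va + vw),
        pct_within=100.0 * vw / (va + vw),
    )


def amova_one_level(
    d: DistanceMatrix,
    groups: list[str] | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    squared: bool = False,
) -> AmovaResult:
    """One-level AMOVA of a distance matrix over group labels.

    ``squared`` declares that ``d`` already holds squared distances;
    otherwise entries are squared internally. The permutation p-value uses
    the (b + 1) / (m + 1) estimator on PhiPT with group labels shuffled.
    """
    groups = np.asarray(groups)
    if len(groups) != d.n:
        raise ValueError("one group label per sample required")
    names, codes = np.unique(groups, return_inverse=True)
    k = len(names)
    if k < 2:
        raise ValueError("AMOVA needs at least two groups")
    sq = d.values if squared else d.values**2

    ss_a, ss_w, ms_a, ms_w, n0, va_raw, phi, phi_raw = _phi_from_ss(sq, codes, k)
    va, vw = max(va_raw, 0.0), ms_w
    denom = va + vw
    res = AmovaResult(
        df_among=k - 1,
        df_within=d.n - k,
        ss_among=ss_a,
        ss_within=ss_w,
        ms_among=ms_a,
        ms_within=ms_w,
        va=va,
        va_raw=va_raw,
        vw=vw,
        n0=n0,
        phi_pt=phi,
        pct_among=100.0 * va / denom if denom > 0 else np.nan,
        pct_within=100.0 * vw / denom if denom > 0 else np.nan,
    )
    if n_perm >= 1 and np.isfinite(phi_raw):
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(codes)
            phi_p = _phi_from_ss(sq, perm, k)[7]
            if np.isfinite(phi_p) and phi_p >= phi_raw:
                hits += 1
        res.p_value = (hits + 1) / (n_perm + 1)
        res.n_permutations = n_perm
    return res


def squared_euclidean_matrix(g: GenotypeMatrix) -> DistanceMatrix:
    """Squared Euclidean dosage distances, the default AMOVA input."""
    from heterogroup.distance import euclidean_distance

    d = euclidean_distance(g)
    return DistanceMatrix(labels=d.labels, values=d.values**2, metric_name="sq_euclidean")


@dataclass
class PairwiseDiff:
    group_names: list[str]
    phi: np.ndarray  # k x k, symmetric content stored below diagonal
    p: np.ndarray  # permutation p above diagonal (NaN below)
    nm: np.ndarray  # gene-flow companion

    def to_frame(self) -> pd.DataFrame:
        k = len(self.group_names)
        out = np.full((k, k), np.nan)
        for i in range(k):
            for j in range(k):
                if i > j:
                    out[i, j] = self.phi[i, j]
                elif i < j:
                    out[i, j] = self.p[i, j]
                else:
                    out[i, j] = 0.0
        return pd.DataFrame(out, index=self.group_names, columns=self.group_names)


def pairwise_phi(
    d: DistanceMatrix,
    groups: list[str] | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    squared: bool = False,
) -> PairwiseDiff:
    """PhiPT, permutation p and gene flow for every pair of groups."""
    groups = np.asarray(groups)
    names = list(np.unique(groups))
    k = len(names)
    if k < 2:
        raise ValueError("need at least two groups")
    phi = np.zeros((k, k))
    p = np.full((k, k), np.nan)
    nm = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            idx = np.flatnonzero(np.isin(groups, [names[i], names[j]]))
            sub = DistanceMatrix(
                labels=[d.labels[t] for t in idx],
                values=d.values[np.ix_(idx, idx)],
                metric_name=d.metric_name,
            )
            res = amova_one_level(
                sub, groups[idx], n_perm=n_perm, seed=seed + 7919 * (i * k + j),
                squared=squared,
            )
            phi[i, j] = phi[j, i] = res.phi_pt
            p[i, j] = p[j, i] = res.p_value if res.p_value is not None else np.nan
            nm[i, j] = nm[j, i] = gene_flow(res.phi_pt) if res.phi_pt > 0 else np.inf
    return PairwiseDiff(group_names=names, phi=phi, p=p, nm=nm)


def gene_flow(phi: float) -> float:
    """Effective migrants per generation: Nm = (1 - Phi) / (2 Phi)."""
    if phi > 1.0:
        raise ValueError(f"differentiation {phi} exceeds 1")
    if phi <= 0.0:
        return float("inf")
    return (1.0 - phi) / (2.0 * phi)


def interpret_fst(phi: float) -> str:
    """Bin a differentiation value: low / moderate / high / very high."""
    if phi < 0:
        return "low"
    if phi <= 0.05:
        return "low"
    if phi <= 0.15:
        return "moderate"
    if phi <= 0.25:
        return "high"
    return "very high"
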