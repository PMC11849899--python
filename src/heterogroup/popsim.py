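"""Synthetic structured inbred panels under the Balding-Nichols model.

The generator emulates an elite inbred breeding panel: a few hundred
near-homozygous individuals drawn from a small number of founder populations
with moderate differentiation, plus an admixed fraction. Subpopulation
allele frequencies follow the Balding-Nichols construction,

    p_ms ~ Beta(p_m (1 - F)/F, (1 - p_m)(1 - F)/F),

so that E[p_ms] = p_m and the among-population variance corresponds to the
differentiation parameter F (an Fst analogue). Repeated selfing of the lines
is collapsed into a residual observed-heterozygosity target rather than an
explicit pedigree: latent Hardy-Weinberg heterozygotes are kept with
probability residual_het / E[het] and otherwise collapsed to a random
homozygote. Loci are independent (no linkage disequilibrium); downstream
statistics in this package are unlinked-marker statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from heterogroup.genotype_io import MISSING, GenotypeMatrix


@dataclass
class SimConfig:
    """Parameters of the synthetic panel.

    Defaults mirror a three-founder elite maize inbred panel: 376 lines in
    subpopulations of 180/137/59, 1904 SNPs on 10 chromosomes, F = 0.10,
    ancestral MAF uniform on (0.1, 0.5] (mean panel MAF near 0.29), residual
    observed heterozygosity 0.02 (S7-level homozygosity), and a 10% admixed
    fraction.
    """

    n_subpops: int = 3
    n_per_subpop: list[int] = field(default_factory=lambda: [180, 137, 59])
    n_markers: int = 1904
    n_chromosomes: int = 10
    fst: float = 0.10
    ancestral_maf_range: tuple[float, float] = (0.1, 0.5)
    residual_het: float = 0.02
    admix_fraction: float = 0.10
    admix_alpha: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        if len(self.n_per_subpop) != self.n_subpops:
            raise ValueError("len(n_per_subpop) must equal n_subpops")
        if not 0.0 < self.fst < 1.0:
            raise ValueError(f"fst={self.fst} outside (0, 1)")
        if not 0.0 <= self.residual_het <= 1.0:
            raise ValueError(f"residual_het={self.residual_het} outside [0, 1]")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0.0 <= self.admix_fraction <= 1.0:
            raise ValueError("admix_fraction outside [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate outside [0, 1)")


@dataclass
class SimTruth:
    """Ground truth of a simulated panel, for parameter-recovery tests."""

    subpop: list[int]  # per-individual majority/origin subpopulation (0-based)
    ancestry: np.ndarray  # individuals x subpops, rows sum to 1
    is_admixed: np.ndarray  # boolean per individual
    ancestral_freq: np.ndarray  # per marker
    subpop_freq: np.ndarray  # subpops x markers

    def to_frame(self, samples: list[str]) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sample_id": samples,
                "subpop": [f"pop{s + 1}" for s in self.subpop],
                "is_admixed": self.is_admixed.astype(bool),
            }
        )
        for k in range(self.ancestry.shape[1]):
            df[f"q_pop{k + 1}"] = self.ancestry[:, k]
        return df


def simulate_panel(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw a structured, near-homozygous genotype panel.

    Returns the panel as a :class:`GenotypeMatrix` (pedigree labels set to
    the true origin subpopulation) together with the generating truth. The
    same config, including seed, gives bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_markers
    k = cfg.n_subpops
    n = int(sum(cfg.n_per_subpop))

    lo, hi = cfg.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=m)
    a = p_anc * (1.0 - cfg.fst) / cfg.fst
    b = (1.0 - p_anc) * (1.0 - cfg.fst) / cfg.fst
    p_sub = rng.beta(a, b, size=(k, m))
    # keep loci segregating in at least one subpopulation
    p_sub = np.clip(p_sub, 1e-6, 1.0 - 1e-6)

    subpop = np.repeat(np.arange(k), cfg.n_per_subpop)
    n_admix = int(round(cfg.admix_fraction * n)) if k > 1 else 0
    admixed_idx = rng.choice(n, size=n_admix, replace=False) if n_admix else np.array([], dtype=int)
    is_admixed = np.zeros(n, dtype=bool)
    is_admixed[admixed_idx] = True

    ancestry = np.zeros((n, k))
    ancestry[np.arange(n), subpop] = 1.0
    if n_admix:
        ancestry[admixed_idx] = rng.dirichlet(np.full(k, cfg.admix_alpha), size=n_admix)
        # the meaningful origin label of an admixed line is its majority ancestry
        subpop = subpop.copy()
        subpop[admixed_idx] = ancestry[admixed_idx].argmax(axis=1)

    # per-individual, per-locus origin subpopulation
    origin = np.broadcast_to(subpop[:, None], (n, m)).copy()
    if n_admix:
        cum = np.cumsum(ancestry[admixed_idx], axis=1)
        u = rng.random((n_admix, m))
        origin[admixed_idx] = (u[:, :, None] > cum[:, None, :]).sum(axis=2)

    p = p_sub[origin, np.arange(m)[None, :]]  # n x m individual allele frequency
    u1 = rng.random((n, m)) < p
    u2 = rng.random((n, m)) < p
    dosage = (u1.astype(np.int8) + u2.astype(np.int8))

    # collapse excess heterozygosity toward the residual target
    het = dosage == 1
    e_het = float(np.mean(2.0 * p * (1.0 - p)))
    if e_het > 0:
        keep_prob = cfg.residual_het / e_het
        if keep_prob > 1.0:
            warnings.warn(
                f"residual_het={cfg.residual_het} exceeds expected Hardy-Weinberg "
                f"heterozygosity {e_het:.4f}; leaving heterozygosity at the HW level",
                stacklevel=2,
            )
            keep_prob = 1.0
        collapse = het & (rng.random((n, m)) >= keep_prob)
        to_alt = rng.random((n, m)) < 0.5
        dosage[collapse & to_alt] = 2
        dosage[collapse & ~to_alt] = 0

    if cfg.missing_rate > 0:
        dosage[rng.random((n, m)) < cfg.missing_rate] = MISSING

    chrom = (np.arange(m) % cfg.n_chromosomes) + 1
    pos = (np.arange(m) // cfg.n_chromosomes + 1) * 1000
    alleles = np.array(["A", "C", "G", "T"])
    ref = alleles[rng.integers(0, 4, size=m)]
    alt = np.array([rng.choice([x for x in "ACGT" if x != r]) for r in ref])
    markers = pd.DataFrame(
        {
            "marker_id": [f"snp_{j + 1:05d}" for j in range(m)],
            "chrom": chrom.astype(str),
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "multiallelic": False,
            "is_indel": False,
        }
    )
    samples = [f"IND{idx + 1:04d}" for idx in range(n)]
    pedigree = {s: f"pop{subpop[idx] + 1}" for idx, s in enumerate(samples)}
    g = GenotypeMatrix(samples=samples, markers=markers, dosage=dosage, pedigree=pedigree)
    truth = SimTruth(
        subpop=list(subpop),
        ancestry=ancestry,
        is_admixed=is_admixed,
        ancestral_freq=p_anc,
        subpop_freq=p_sub,
    )
    return g, truth


def simulate_lnp_table(
    k_max: int,
    true_k: int,
    replicates: int = 5,
    seed: int = 0,
    base: float = -50_000.0,
    rise: float = 2_000.0,
    plateau_slope: float = 50.0,
    noise_sd: float = 30.0,
) -> pd.DataFrame:
    """Simulate a STRUCTURE-style log-probability table for K = 1..k_max.

    The mean curve rises steeply by ``rise`` per K up to ``true_k`` and then
    flattens to ``plateau_slope`` per K, with Gaussian replicate noise of
    ``noise_sd`` — the canonical shape on which the Evanno second-difference
    statistic peaks at ``true_k``. Columns: K, replicate, lnp.
    """
    if not 1 <= true_k <= k_max:
        raise ValueError("need 1 <= true_k <= k_max")
    if replicates < 2:
        raise ValueError("need >= 2 replicates per K (Delta-K uses a standard deviation)")
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(1, k_max + 1):
        mean = base + rise * min(k, true_k) + plateau_slope * max(0, k - true_k)
        for r in range(1, replicates + 1):
            rows.append((k, r, mean + rng.normal(0.0, noise_sd)))
    return pd.DataFrame(rows, columns=["K", "replicate", "lnp"])
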