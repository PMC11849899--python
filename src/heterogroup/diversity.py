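"""Per-marker and panel-level diversity indices.

Per-marker: minor allele frequency, observed/expected heterozygosity and
polymorphism information content (PIC). Panel-level: arithmetic means per
chromosome and genome-wide, plus Shannon, inverse-Simpson and richness
indices computed on multilocus-genotype classes (distinct dosage rows) per
chromosome and genome-wide. PIC is offered in both Botstein's form
(1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2, bounded by 0.375 for a biallelic
marker) and the gene-diversity form (1 - sum p_i^2, bounded by 0.5);
reports name the method used.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from heterogroup.genotype_io import MISSING, GenotypeMatrix


def allele_freq(g: GenotypeMatrix) -> pd.DataFrame:
    """Alternate-allele frequency and MAF per marker.

    Denominators are pairwise complete: 2 x (non-missing call count). Markers
    with no calls get NaN and are excluded from aggregates downstream.
    """
    ok = g.dosage != MISSING
    n_ok = ok.sum(axis=0)
    alt = np.where(ok, g.dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = alt / (2.0 * n_ok)
    freq = np.where(n_ok > 0, freq, np.nan)
    return pd.DataFrame(
        {
            "marker_id": g.markers["marker_id"],
            "alt_freq": freq,
            "maf": np.minimum(freq, 1.0 - freq),
        }
    )


def heterozygosity(g: GenotypeMatrix) -> pd.DataFrame:
    """Observed (fraction of het calls) and expected (2p(1-p)) heterozygosity."""
    ok = g.dosage != MISSING
    n_ok = ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        oh = ((g.dosage == 1) & ok).sum(axis=0) / n_ok
    oh = np.where(n_ok > 0, oh, np.nan)
    p = allele_freq(g)["alt_freq"].to_numpy()
    return pd.DataFrame(
        {"marker_id": g.markers["marker_id"], "obs_het": oh, "exp_het": 2.0 * p * (1.0 - p)}
    )


def pic(freqs: np.ndarray, method: str = "botstein") -> float | np.ndarray:
    """Polymorphism information content from an allele-frequency vector.

    ``freqs`` may be a single frequency vector (sums to 1) or a 2-D array of
    one vector per row. ``botstein``: 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2;
    ``gene_diversity``: 1 - sum p_i^2.
    """
    p = np.atleast_2d(np.asarray(freqs, dtype=float))
    sums = p.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("allele frequencies must sum to 1")
    sq = (p**2).sum(axis=1)
    if method == "gene_diversity":
        out = 1.0 - sq
    elif method == "botstein":
        # sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4
        out = 1.0 - sq - (sq**2 - (p**4).sum(axis=1))
    else:
        raise ValueError(f"unknown PIC method {method!r}")
    return float(out[0]) if np.asarray(freqs).ndim == 1 else out


def marker_stats(g: GenotypeMatrix, pic_method: str = "botstein") -> pd.DataFrame:
    """Per-marker table: maf, obs_het, exp_het, pic, call_rate, chromosome."""
    af = allele_freq(g)
    het = heterozygosity(g)
    p = af["alt_freq"].to_numpy()
    freq_pairs = np.column_stack([1.0 - p, p])
    pic_vals = np.full(len(p), np.nan)
    okp = np.isfinite(p)
    if okp.any():
        pic_vals[okp] = pic(freq_pairs[okp], method=pic_method)
    return pd.DataFrame(
        {
            "marker_id": g.markers["marker_id"],
            "chrom": g.markers["chrom"].astype(str),
            "maf": af["maf"],
            "obs_het": het["obs_het"],
            "exp_het": het["exp_het"],
            "pic": pic_vals,
            "call_rate": (g.dosage != MISSING).mean(axis=0),
        }
    )


def abundance_indices(class_counts: np.ndarray) -> tuple[float, float, int]:
    """Shannon entropy, inverse Simpson and richness of a class-count vector."""
    c = np.asarray(class_counts, dtype=float)
    if c.size == 0 or (c < 0).any() or c.sum() <= 0:
        raise ValueError("class counts must be non-negative with a positive total")
    q = c[c > 0] / c.sum()
    shannon_h = float(-(q * np.log(q)).sum())
    inv_simpson = float(1.0 / (q**2).sum())
    return shannon_h, inv_simpson, int((c > 0).sum())


def _genotype_class_counts(dosage: np.ndarray) -> np.ndarray:
    """Counts of distinct multilocus genotype rows (missing pattern included)."""
    _, counts = np.unique(dosage, axis=0, return_counts=True)
    return counts


def summarize_by_chromosome(stats: pd.DataFrame, g: GenotypeMatrix) -> pd.DataFrame:
    """Aggregate marker stats per chromosome plus min/mean/max and genome rows.

    Mean OH/EH/MAF/PIC are arithmetic means over markers; Shannon/inverse
    Simpson/richness are computed on distinct multilocus-genotype classes
    restricted to each chromosome (and genome-wide for the summary rows).
    """
    if len(stats) != g.n_markers:
        raise ValueError("stats not aligned with genotype matrix markers")
    chroms = list(dict.fromkeys(g.markers["chrom"].astype(str)))
    cols = ["maf", "obs_het", "exp_het", "pic"]
    rows = []
    for chrom in chroms:
        mask = (g.markers["chrom"].astype(str) == chrom).to_numpy()
        sub = stats.loc[mask, cols]
        if mask.sum() == 0:
            rows.append({"chrom": chrom, "n_markers": 0})
            continue
        h, d, s = abundance_indices(_genotype_class_counts(g.dosage[:, mask]))
        rows.append(
            {
                "chrom": chrom,
                "n_markers": int(mask.sum()),
                **{f"mean_{c}": sub[c].mean() for c in cols},
                "shannon_h": h,
                "inv_simpson": d,
                "richness": s,
            }
        )
    per_chrom = pd.DataFrame(rows)
    h, d, s = abundance_indices(_genotype_class_counts(g.dosage))
    summary = [
        {
            "chrom": "Min",
            "n_markers": per_chrom["n_markers"].min(),
            **{f"mean_{c}": stats[c].min() for c in cols},
        },
        {
            "chrom": "Average",
            "n_markers": per_chrom["n_markers"].mean(),
            **{f"mean_{c}": stats[c].mean() for c in cols},
            "shannon_h": h,
            "inv_simpson": d,
            "richness": s,
        },
        {
            "chrom": "Max",
            "n_markers": per_chrom["n_markers"].max(),
            **{f"mean_{c}": stats[c].max() for c in cols},
        },
    ]
    out = pd.concat([per_chrom, pd.DataFrame(summary)], ignore_index=True)
    out.attrs["abundance_unit"] = "multilocus genotype classes"
    out.attrs["pic_method"] = stats.attrs.get("pic_method", "botstein")
    return out
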