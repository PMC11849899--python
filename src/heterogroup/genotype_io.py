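"""Genotype matrix container, HapMap/VCF readers and writers, and SNP QC.

Dosages count copies of the alternate allele (0, 1, 2); missing calls use a
single sentinel (:data:`MISSING`). Positions are 1-based as in both source
formats. All downstream statistics treat missing entries with
pairwise-complete denominators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

HAPMAP_META_COLUMNS = [
    "rs#",
    "alleles",
    "chrom",
    "pos",
    "strand",
    "assembly#",
    "center",
    "protLSID",
    "assayLSID",
    "panelLSID",
    "QCcode",
]

MARKER_COLUMNS = ["marker_id", "chrom", "pos", "ref", "alt", "multiallelic", "is_indel"]


class GenotypeFormatError(ValueError):
    """Malformed file structure (header, columns, FORMAT keys)."""


class GenotypeDataError(ValueError):
    """Structurally valid file with an inconsistent genotype record."""


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix with marker map and sample labels.

    Parameters
    ----------
    samples
        Ordered unique sample identifiers.
    markers
        DataFrame with columns ``marker_id, chrom, pos, ref, alt`` and the
        flag columns ``multiallelic, is_indel`` (filled with False when the
        source format cannot express them).
    dosage
        ``(n_samples, n_markers)`` integer array in {0, 1, 2, MISSING}.
    pedigree
        Optional per-sample source-population label.
    """

    samples: list[str]
    markers: pd.DataFrame
    dosage: np.ndarray
    pedigree: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.markers = self.markers.reset_index(drop=True)
        for col in ("multiallelic", "is_indel"):
            if col not in self.markers.columns:
                self.markers[col] = False
        self.validate()

    def validate(self) -> None:
        n, m = self.dosage.shape
        if n != len(self.samples):
            raise ValueError(f"dosage has {n} rows but {len(self.samples)} samples")
        if m != len(self.markers):
            raise ValueError(f"dosage has {m} columns but {len(self.markers)} markers")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample identifiers are not unique")
        ids = self.markers["marker_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate marker identifier {dup!r}")
        if (self.markers["pos"] < 0).any():
            raise ValueError("negative marker position")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"dosage[{i},{j}]={self.dosage[i, j]} outside {{0,1,2,{MISSING}}}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def dosage_float(self) -> np.ndarray:
        """Dosages as float with missing entries as NaN."""
        x = self.dosage.astype(float)
        x[self.dosage == MISSING] = np.nan
        return x

    def subset(
        self,
        sample_idx: Sequence[int] | np.ndarray | None = None,
        marker_idx: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        samples = [self.samples[i] for i in si]
        ped = None
        if self.pedigree is not None:
            ped = {s: self.pedigree[s] for s in samples if s in self.pedigree}
        return GenotypeMatrix(
            samples=samples,
            markers=self.markers.iloc[mi].reset_index(drop=True),
            dosage=self.dosage[np.ix_(si, mi)],
            pedigree=ped,
        )

    def pedigree_labels(self, missing: str = "unknown") -> list[str]:
        if self.pedigree is None:
            return [missing] * self.n_samples
        return [self.pedigree.get(s, missing) for s in self.samples]


@dataclass(frozen=True)
class QcThresholds:
    """Marker/sample filtering thresholds.

    ``marker_call_rate_min`` is per marker (fraction of non-missing calls);
    ``sample_missing_max`` is per sample. MAF is computed on retained samples
    with missing calls excluded from denominators.
    """

    maf_min: float = 0.05
    marker_call_rate_min: float = 0.90
    sample_missing_max: float = 0.20
    biallelic_only: bool = True
    exclude_indels: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError(f"maf_min={self.maf_min} outside [0, 0.5]")
        for name in ("marker_call_rate_min", "sample_missing_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QcReport:
    n_markers_in: int
    n_markers_out: int
    n_samples_in: int
    n_samples_out: int
    removed_multiallelic: int = 0
    removed_indel: int = 0
    removed_call_rate: int = 0
    removed_maf: int = 0
    removed_samples_missing: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.__dict__, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


# ---------------------------------------------------------------------------
# HapMap


def read_hapmap(path: str | Path, pedigree: dict[str, str] | None = None) -> GenotypeMatrix:
    """Read a tab-delimited HapMap genotype file.

    Genotype cells are two-letter IUPAC pairs (``AA``, ``AT``, ...) or ``NN``
    for missing. The alternate allele is the second allele of the ``alleles``
    column; heterozygotes in either letter order map to dosage 1.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = [c for c in HAPMAP_META_COLUMNS if c not in df.columns]
    if missing_cols:
        raise GenotypeFormatError(
            f"HapMap header is missing required column(s): {', '.join(missing_cols)}"
        )
    sample_cols = [c for c in df.columns if c not in HAPMAP_META_COLUMNS]
    if not sample_cols:
        raise GenotypeFormatError("HapMap file contains no sample columns")

    alleles = df["alleles"].str.split("/", expand=True)
    if alleles.shape[1] < 2 or alleles.isna().any().any():
        bad = df.loc[alleles.isna().any(axis=1), "rs#"].iloc[0]
        raise GenotypeFormatError(f"marker {bad!r}: alleles field is not 'X/Y'")
    markers = pd.DataFrame(
        {
            "marker_id": df["rs#"],
            "chrom": df["chrom"].astype(str),
            "pos": df["pos"].astype(int),
            "ref": alleles[0],
            "alt": alleles[1],
            "multiallelic": alleles.shape[1] > 2 and alleles[2].notna(),
            "is_indel": False,
        }
    )

    n, m = len(sample_cols), len(df)
    dosage = np.full((n, m), MISSING, dtype=np.int8)
    cells = df[sample_cols].to_numpy(dtype=str)  # markers x samples
    ref = markers["ref"].to_numpy()
    alt = markers["alt"].to_numpy()
    for j in range(m):
        for i, cell in enumerate(cells[j]):
            if cell == "NN":
                continue
            if len(cell) != 2:
                raise GenotypeDataError(
                    f"marker {markers['marker_id'][j]!r}, sample {sample_cols[i]!r}: "
                    f"genotype {cell!r} is not a two-letter call"
                )
            d = 0
            for letter in cell:
                if letter == alt[j]:
                    d += 1
                elif letter != ref[j]:
                    raise GenotypeDataError(
                        f"marker {markers['marker_id'][j]!r}, sample {sample_cols[i]!r}: "
                        f"allele {letter!r} not in pair {ref[j]}/{alt[j]}"
                    )
            dosage[i, j] = d
    return GenotypeMatrix(samples=sample_cols, markers=markers, dosage=dosage, pedigree=pedigree)


def write_hapmap(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as a HapMap table (inverse of :func:`read_hapmap`)."""
    ref = g.markers["ref"].to_numpy()
    alt = g.markers["alt"].to_numpy()
    rows = []
    for j in range(g.n_markers):
        mk = g.markers.iloc[j]
        code = {0: ref[j] * 2, 1: ref[j] + alt[j], 2: alt[j] * 2, MISSING: "NN"}
        row = [
            mk["marker_id"],
            f"{ref[j]}/{alt[j]}",
            str(mk["chrom"]),
            str(int(mk["pos"])),
            "+",
            "NA",
            "NA",
            "NA",
            "NA",
            "NA",
            "NA",
        ]
        row.extend(code[int(d)] for d in g.dosage[:, j])
        rows.append(row)
    out = pd.DataFrame(rows, columns=HAPMAP_META_COLUMNS + list(g.samples))
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | Path, gq_min: float | None = 20.0,
             pedigree: dict[str, str] | None = None) -> GenotypeMatrix:
    """Read a VCF (v4.x, GT required) into a GenotypeMatrix.

    GT ``0/0`` -> 0, ``0/1``/``1/0`` -> 1, ``1/1`` -> 2, ``./.`` -> missing;
    phased separators are accepted. Records with more than one ALT allele or
    with indel/symbolic alleles are retained but flagged ``multiallelic`` /
    ``is_indel`` for the filter stage. When a GQ FORMAT field is present,
    calls with GQ below ``gq_min`` are set to missing (pass ``gq_min=None``
    to disable).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[dict] = []
    dosages: list[np.ndarray] = []
    for var in vcf:
        if "GT" not in (var.FORMAT or []):
            raise GenotypeFormatError(
                f"record {var.CHROM}:{var.POS} has no GT field in FORMAT"
            )
        alts = list(var.ALT) if var.ALT else []
        alt = alts[0] if alts else "."
        symbolic = any(a.startswith("<") or a in (".", "*") for a in alts)
        is_indel = symbolic or len(var.REF) != 1 or any(len(a) != 1 for a in alts if not a.startswith("<"))
        d = np.full(len(samples), MISSING, dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            if len(gt) != 3:
                raise GenotypeDataError(
                    f"record {var.CHROM}:{var.POS}, sample {samples[i]!r}: non-diploid GT"
                )
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                continue
            d[i] = (1 if a > 0 else 0) + (1 if b > 0 else 0)
        if gq_min is not None and "GQ" in (var.FORMAT or []):
            gq = var.format("GQ")
            if gq is not None:
                low = np.asarray(gq).reshape(len(samples)) < gq_min
                d[low] = MISSING
        rows.append(
            {
                "marker_id": var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "ref": var.REF,
                "alt": alt,
                "multiallelic": len(alts) > 1,
                "is_indel": bool(is_indel),
            }
        )
        dosages.append(d)
    markers = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    dosage = (
        np.stack(dosages, axis=1) if dosages else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples=samples, markers=markers, dosage=dosage, pedigree=pedigree)


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 with GT calls (inverse of :func:`read_vcf`)."""
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=heterogroup\n")
        for chrom in pd.unique(g.markers["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.samples) + "\n")
        # records are written in matrix order (not coordinate-sorted) so a
        # write/read round-trip preserves the marker map exactly
        for j in range(g.n_markers):
            mk = g.markers.iloc[j]
            calls = "\t".join(gt_code[int(d)] for d in g.dosage[:, j])
            fh.write(
                f"{mk['chrom']}\t{int(mk['pos'])}\t{mk['marker_id']}\t{mk['ref']}\t"
                f"{mk['alt']}\t.\t.\t.\tGT\t{calls}\n"
            )


def read_pedigree(path: str | Path) -> dict[str, str]:
    """Read a 2-column CSV (sample_id, source_population) into a dict."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise GenotypeFormatError("pedigree CSV needs 2 columns: sample_id, source_population")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


# ---------------------------------------------------------------------------
# QC


def _marker_maf(dosage: np.ndarray) -> np.ndarray:
    ok = dosage != MISSING
    n_ok = ok.sum(axis=0)
    alt = np.where(ok, dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = alt / (2.0 * n_ok)
    return np.minimum(freq, 1.0 - freq)


def apply_qc(g: GenotypeMatrix, t: QcThresholds | None = None) -> tuple[GenotypeMatrix, QcReport]:
    """Apply SNP quality control and return the filtered matrix plus a report.

    Rules apply in order, each marker tallied under the first rule it fails:
    biallelic / no-indel, then marker call rate, then MAF; finally samples
    whose missing fraction exceeds the sample threshold are dropped.
    """
    if t is None:
        t = QcThresholds()
    if g.n_markers == 0 or g.n_samples == 0:
        raise ValueError("cannot QC an empty genotype matrix")

    report = QcReport(
        n_markers_in=g.n_markers,
        n_markers_out=0,
        n_samples_in=g.n_samples,
        n_samples_out=0,
    )
    keep = np.ones(g.n_markers, dtype=bool)

    if t.biallelic_only:
        fail = g.markers["multiallelic"].to_numpy(dtype=bool) & keep
        report.removed_multiallelic = int(fail.sum())
        keep &= ~fail
    if t.exclude_indels:
        fail = g.markers["is_indel"].to_numpy(dtype=bool) & keep
        report.removed_indel = int(fail.sum())
        keep &= ~fail

    ok = g.dosage != MISSING
    call_rate = ok.mean(axis=0)
    fail = (call_rate < t.marker_call_rate_min) & keep
    report.removed_call_rate = int(fail.sum())
    keep &= ~fail

    maf = _marker_maf(g.dosage)
    fail = keep & (~np.isfinite(maf) | (maf < t.maf_min))
    report.removed_maf = int(fail.sum())
    keep &= ~fail

    if not keep.any():
        raise ValueError("QC removed every marker; relax the thresholds")

    sub = g.dosage[:, keep]
    sample_missing = (sub == MISSING).mean(axis=1)
    keep_samples = sample_missing <= t.sample_missing_max
    report.removed_samples_missing = int((~keep_samples).sum())
    if not keep_samples.any():
        raise ValueError("QC removed every sample; relax the thresholds")

    out = g.subset(np.flatnonzero(keep_samples), np.flatnonzero(keep))
    report.n_markers_out = out.n_markers
    report.n_samples_out = out.n_samples
    return out, report
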