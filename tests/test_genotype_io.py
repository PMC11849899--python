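"""HapMap/VCF round-trips, dosage coding and QC filtering rules."""

import numpy as np
import pytest

from conftest import make_matrix
from heterogroup.genotype_io import (
    MISSING,
    GenotypeDataError,
    GenotypeFormatError,
    QcThresholds,
    apply_qc,
    read_hapmap,
    read_pedigree,
    read_vcf,
    write_hapmap,
    write_vcf,
)


def hapmap_text(cells, alleles="A/T"):
    header = (
        "rs#\talleles\tchrom\tpos\tstrand\tassembly#\tcenter\tprotLSID\t"
        "assayLSID\tpanelLSID\tQCcode\ts1\ts2\n"
    )
    body = "".join(
        f"m{j}\t{alleles}\t1\t{100 * (j + 1)}\t+\tNA\tNA\tNA\tNA\tNA\tNA\t"
        + "\t".join(row) + "\n"
        for j, row in enumerate(cells)
    )
    return header + body


class TestHapmap:
    @pytest.mark.parametrize(
        "cell,expected",
        [("AA", 0), ("AT", 1), ("TA", 1), ("TT", 2), ("NN", MISSING)],
    )
    def test_dosage_coding(self, tmp_path, cell, expected):
        path = tmp_path / "g.hmp.txt"
        path.write_text(hapmap_text([[cell, "AA"]]))
        g = read_hapmap(path)
        assert g.dosage[0, 0] == expected

    def test_round_trip(self, tmp_path):
        g = make_matrix([[0, 1, 2, MISSING], [2, 1, 0, 0]])
        path = tmp_path / "rt.hmp.txt"
        write_hapmap(g, path)
        back = read_hapmap(path)
        assert back.samples == g.samples
        np.testing.assert_array_equal(back.dosage, g.dosage)
        assert list(back.markers["marker_id"]) == list(g.markers["marker_id"])
        assert list(back.markers["pos"]) == list(g.markers["pos"])

    def test_missing_header_column_named(self, tmp_path):
        path = tmp_path / "bad.hmp.txt"
        path.write_text(hapmap_text([["AA", "AA"]]).replace("alleles", "als"))
        with pytest.raises(GenotypeFormatError, match="alleles"):
            read_hapmap(path)

    def test_foreign_allele_names_marker_and_sample(self, tmp_path):
        path = tmp_path / "bad.hmp.txt"
        path.write_text(hapmap_text([["AG", "AA"]]))
        with pytest.raises(GenotypeDataError, match="m0.*s1"):
            read_hapmap(path)


class TestVcf:
    def test_round_trip(self, tmp_path):
        g = make_matrix([[0, 1, 2], [2, MISSING, 0], [1, 1, 1]])
        path = tmp_path / "rt.vcf"
        write_vcf(g, path)
        back = read_vcf(path)
        assert back.samples == g.samples
        np.testing.assert_array_equal(back.dosage, g.dosage)

    def test_gt_coding_including_phased(self, tmp_path):
        path = tmp_path / "g.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc\td\n"
            "1\t100\tm0\tA\tT\t.\t.\t.\tGT\t0|1\t1/0\t1|1\t./.\n"
        )
        g = read_vcf(path)
        assert list(g.dosage[:, 0]) == [1, 1, 2, MISSING]

    def test_multiallelic_and_indel_flagged_not_dropped(self, tmp_path):
        path = tmp_path / "g.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\n"
            "1\t100\tm0\tA\tT,C\t.\t.\t.\tGT\t0/1\t0/0\n"
            "1\t200\tm1\tAT\tA\t.\t.\t.\tGT\t0/0\t1/1\n"
            "1\t300\tm2\tA\tT\t.\t.\t.\tGT\t0/0\t1/1\n"
        )
        g = read_vcf(path)
        assert g.n_markers == 3
        assert list(g.markers["multiallelic"]) == [True, False, False]
        assert list(g.markers["is_indel"]) == [False, True, False]
        filtered, report = apply_qc(g, QcThresholds(maf_min=0.0, marker_call_rate_min=0.0))
        assert list(filtered.markers["marker_id"]) == ["m2"]
        assert report.removed_multiallelic == 1 and report.removed_indel == 1

    def test_gq_below_threshold_set_missing(self, tmp_path):
        path = tmp_path / "g.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\n"
            "1\t100\tm0\tA\tT\t.\t.\t.\tGT:GQ\t0/1:10\t1/1:99\n"
        )
        g = read_vcf(path, gq_min=20)
        assert list(g.dosage[:, 0]) == [MISSING, 2]
        g2 = read_vcf(path, gq_min=None)
        assert list(g2.dosage[:, 0]) == [1, 2]


class TestQc:
    def test_maf_filter_direct_count(self):
        # MAF {0.01, 0.30, 0.00} realized over 50 samples with full call rate
        n = 50
        dosage = np.zeros((n, 3), dtype=np.int8)
        dosage[0, 0] = 1  # freq 1/100
        dosage[:30, 1] = 1  # freq 0.30
        g = make_matrix(dosage)
        filtered, report = apply_qc(g, QcThresholds(maf_min=0.05))
        assert filtered.n_markers == 1
        assert report.removed_maf == 2

    def test_permissive_thresholds_identity(self, small_panel):
        g, _ = small_panel
        filtered, report = apply_qc(
            g, QcThresholds(maf_min=0.0, marker_call_rate_min=0.0, sample_missing_max=1.0)
        )
        np.testing.assert_array_equal(filtered.dosage, g.dosage)
        assert report.removed_maf == report.removed_call_rate == 0

    def test_call_rate_rule(self):
        dosage = np.ones((20, 2), dtype=np.int8)
        dosage[:3, 0] = MISSING  # 85% call rate
        g = make_matrix(dosage)
        filtered, report = apply_qc(
            g, QcThresholds(maf_min=0.0, marker_call_rate_min=0.90, sample_missing_max=1.0)
        )
        assert filtered.n_markers == 1
        assert report.removed_call_rate == 1

    def test_idempotent(self, small_panel):
        g, _ = small_panel
        t = QcThresholds(maf_min=0.10, marker_call_rate_min=0.90)
        once, _ = apply_qc(g, t)
        twice, report = apply_qc(once, t)
        np.testing.assert_array_equal(once.dosage, twice.dosage)
        assert report.n_markers_in == report.n_markers_out
        assert report.removed_samples_missing == 0

    def test_marker_rules_order_independent_without_sample_removal(self, small_panel):
        g, _ = small_panel
        t = QcThresholds(maf_min=0.15, marker_call_rate_min=0.95, sample_missing_max=1.0)
        filtered, _ = apply_qc(g, t)
        ok = (g.dosage != MISSING).mean(axis=0) >= t.marker_call_rate_min
        freq = np.where(g.dosage == MISSING, 0, g.dosage).sum(axis=0) / (
            2.0 * (g.dosage != MISSING).sum(axis=0)
        )
        maf_ok = np.minimum(freq, 1 - freq) >= t.maf_min
        joint = set(g.markers["marker_id"][ok & maf_ok])
        assert set(filtered.markers["marker_id"]) == joint

    def test_all_removed_raises(self):
        g = make_matrix(np.zeros((5, 3), dtype=np.int8))  # all monomorphic
        with pytest.raises(ValueError, match="every marker"):
            apply_qc(g, QcThresholds(maf_min=0.05))

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            QcThresholds(maf_min=0.7)


def test_pedigree_reader(tmp_path):
    path = tmp_path / "ped.csv"
    path.write_text("sample_id,source_population\na,pop1\nb,pop2\n")
    assert read_pedigree(path) == {"a": "pop1", "b": "pop2"}
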