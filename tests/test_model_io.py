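"""Domain types and file I/O: sorting contracts, heterozygote coercion,
round trips, VCF parsing, BED coordinate conventions."""

import numpy as np
import pandas as pd
import pytest

from haplodyn import io as hio
from haplodyn.model import (MISSING, AnnotationInterval, DataError,
                            GenotypeMatrix, build_matrix)

from conftest import mk_matrix


def write_toy_files(tmp_path, rows, snp_rows, acc_rows):
    gpath = tmp_path / "geno.tsv"
    gpath.write_text("\n".join("\t".join(r) for r in rows) + "\n")
    spath = tmp_path / "snps.tsv"
    spath.write_text("snp_id\tchromosome\tposition_bp\tsource_panel\n"
                     + "\n".join("\t".join(r) for r in snp_rows) + "\n")
    apath = tmp_path / "acc.tsv"
    apath.write_text(
        "accession_id\tgroup\twater_regime\tregistration_year\tregion\n"
        + "\n".join("\t".join(r) for r in acc_rows) + "\n")
    return gpath, spath, apath


SNPS_4 = [["s1", "1", "300", "other"], ["s2", "1", "100", "other"],
          ["s3", "2", "50", "other"], ["s4", "1", "200", "other"]]
ACCS_3 = [["a1", "group1", "irrigated", "", ""],
          ["a2", "group2", "irrigated", "1960", ""],
          ["a3", "group3", "irrigated", "1990", ""]]


def test_read_genotype_table_sorts_by_position(tmp_path):
    rows = [["accession_id", "s1", "s2", "s3", "s4"],
            ["a1", "A", "A", "B", "A"],
            ["a2", "B", "A", "B", "A"],
            ["a3", "A", "B", "A", "B"]]
    g, s, a = write_toy_files(tmp_path, rows, SNPS_4, ACCS_3)
    m = hio.read_genotype_table(g, s, a)
    assert m.calls.shape == (3, 4)
    assert list(m.snps["snp_id"]) == ["s2", "s4", "s1", "s3"]
    # a1's calls follow the SNPs into sorted order
    assert list(m.calls[0]) == [0, 0, 0, 1]


def test_heterozygote_coerced_to_missing(tmp_path):
    rows = [["accession_id", "s1", "s2", "s3", "s4"],
            ["a1", "H", "A", "B", "A"],
            ["a2", "B", "A", "B", "A"],
            ["a3", "A", "B", "A", "B"]]
    g, s, a = write_toy_files(tmp_path, rows, SNPS_4, ACCS_3)
    m = hio.read_genotype_table(g, s, a)
    assert m.het_coerced == 1
    col = list(m.snps["snp_id"]).index("s1")
    assert m.calls[0, col] == MISSING
    assert (m.calls != 2).all()


def test_non_biallelic_column_rejected(tmp_path):
    rows = [["accession_id", "s1", "s2", "s3", "s4"],
            ["a1", "A", "A", "B", "A"],
            ["a2", "C", "A", "B", "A"],
            ["a3", "B", "B", "A", "B"]]
    g, s, a = write_toy_files(tmp_path, rows, SNPS_4, ACCS_3)
    with pytest.raises(DataError, match="non-biallelic"):
        hio.read_genotype_table(g, s, a)


def test_unknown_accession_rejected(tmp_path):
    rows = [["accession_id", "s1", "s2", "s3", "s4"],
            ["aX", "A", "A", "B", "A"]]
    g, s, a = write_toy_files(tmp_path, rows, SNPS_4, ACCS_3)
    with pytest.raises(DataError, match="aX"):
        hio.read_genotype_table(g, s, a)


def test_tied_positions_rejected():
    with pytest.raises(DataError, match="tied"):
        mk_matrix(np.zeros((2, 2)), chromosome=[1, 1],
                  position=[100, 100])


def test_round_trip_exact(tmp_path, toy_panel):
    matrix, _ = toy_panel
    hio.write_matrix(matrix, tmp_path, prefix="rt")
    back = hio.read_matrix(tmp_path, prefix="rt")
    assert np.array_equal(back.calls, matrix.calls)
    assert list(back.snps["snp_id"]) == list(matrix.snps["snp_id"])
    assert list(back.accessions["accession_id"]) == \
        list(matrix.accessions["accession_id"])
    assert list(back.accessions["group"]) == list(matrix.accessions["group"])
    yrs_a = back.accessions["registration_year"].fillna(-1).tolist()
    yrs_b = matrix.accessions["registration_year"].fillna(-1).tolist()
    assert yrs_a == yrs_b


def test_loaded_matrix_never_heterozygous(toy_panel):
    matrix, _ = toy_panel
    assert set(np.unique(matrix.calls)) <= {-1, 0, 1}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta1\ta2\ta3
"""


def write_vcf(tmp_path, body):
    p = tmp_path / "in.vcf"
    p.write_text(VCF_HEADER + body)
    a = tmp_path / "acc.tsv"
    a.write_text(
        "accession_id\tgroup\twater_regime\tregistration_year\tregion\n"
        + "\n".join("\t".join(r) for r in ACCS_3) + "\n")
    return p, a


def test_vcf_het_and_nocall_become_missing(tmp_path):
    body = ("chr1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
            "chr1\t200\trs2\tC\tT\t.\t.\t.\tGT\t./.\t1/1\t0/0\n")
    p, a = write_vcf(tmp_path, body)
    m = hio.read_vcf(p, a)
    assert m.calls.shape == (3, 2)
    assert list(m.calls[:, 0]) == [0, MISSING, 1]
    assert list(m.calls[:, 1]) == [MISSING, 1, 0]


def test_vcf_multiallelic_skipped(tmp_path):
    body = ("chr1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/0\t1/1\n"
            "chr1\t200\trs2\tC\tT,G\t.\t.\t.\tGT\t0/0\t1/1\t2/2\n"
            "chr1\t300\trs3\tC\tT\t.\t.\t.\tGT\t0/0\t1/1\t1/1\n")
    p, a = write_vcf(tmp_path, body)
    m = hio.read_vcf(p, a)
    assert m.n_snps == 2
    assert m.vcf_skipped == 1


def test_vcf_empty_body_errors(tmp_path):
    p, a = write_vcf(tmp_path, "")
    with pytest.raises(DataError, match="no usable records"):
        hio.read_vcf(p, a)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def test_bed_coordinate_conversion(tmp_path):
    path = tmp_path / "out.bed"
    hio.write_bed([AnnotationInterval(1, 100, 200, "x")], path)
    assert path.read_text() == "chr1\t99\t200\tx\n"
    back = hio.read_annotations_bed(path)
    assert back[0].start_bp == 100 and back[0].end_bp == 200


def test_bed_empty_and_long_region(tmp_path):
    path = tmp_path / "empty.bed"
    hio.write_bed([], path)
    assert path.read_text() == ""
    path2 = tmp_path / "long.bed"
    hio.write_bed([AnnotationInterval(11, 11_600_000, 14_558_000, "big")], path2)
    _, start0, end, _ = path2.read_text().split()
    assert int(end) - int(start0) == 2_958_001  # 1-based inclusive span in bp
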