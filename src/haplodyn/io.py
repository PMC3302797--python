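"""Readers and writers for the package's external formats.

Tab-delimited genotype matrices (rows = accessions, columns = SNP ids, cells
drawn from a declared allele alphabet plus heterozygote/no-call codes), SNP
and accession metadata TSVs, VCF input (through pysam), BED output, pedigree
and Q-matrix TSVs, and a PHYLIP square distance matrix writer.

Coordinates are 1-based inclusive internally; BED export converts to 0-based
half-open at the boundary. Heterozygous input calls are coerced to missing
(no-signal) with a logged count, matching the homozygous-inbred assumption of
the analyses.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .model import (ACCESSION_COLUMNS, ALLELE_A, ALLELE_B, MISSING,
                    SNP_COLUMNS, AnnotationInterval, DataError,
                    GenotypeMatrix, build_matrix)

log = logging.getLogger(__name__)

DEFAULT_ALPHABET = ("A", "B")
HET_CODE = "H"
MISSING_CODE = "N"


# ---------------------------------------------------------------------------
# metadata tables
# ---------------------------------------------------------------------------

def read_snp_metadata(path: str | Path) -> pd.DataFrame:
    snps = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    missing_cols = set(SNP_COLUMNS) - set(snps.columns)
    if missing_cols:
        raise DataError(f"SNP metadata lacks columns {sorted(missing_cols)}")
    return snps[SNP_COLUMNS]


def read_accession_metadata(path: str | Path) -> pd.DataFrame:
    acc = pd.read_csv(path, sep="\t", dtype={"accession_id": str, "group": str})
    missing_cols = set(ACCESSION_COLUMNS) - set(acc.columns)
    if missing_cols:
        raise DataError(f"accession metadata lacks columns {sorted(missing_cols)}")
    acc["registration_year"] = pd.to_numeric(
        acc["registration_year"], errors="coerce").astype("Int64")
    return acc[ACCESSION_COLUMNS]


def write_snp_metadata(snps: pd.DataFrame, path: str | Path) -> None:
    snps[SNP_COLUMNS].to_csv(path, sep="\t", index=False)


def write_accession_metadata(acc: pd.DataFrame, path: str | Path) -> None:
    acc[ACCESSION_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotype table
# ---------------------------------------------------------------------------

def read_genotype_table(path: str | Path, snp_meta_path: str | Path,
                        accession_meta_path: str | Path,
                        alphabet: tuple[str, str] | None = DEFAULT_ALPHABET,
                        het_code: str = HET_CODE,
                        missing_code: str = MISSING_CODE) -> GenotypeMatrix:
    """Load a genotype TSV plus its SNP/accession metadata.

    With the default two-symbol ``alphabet``, symbols map positionally to
    allele_a/allele_b, so writing and re-reading a matrix reproduces calls
    exactly. With ``alphabet=None`` the first symbol observed in file order
    within each column becomes allele_a (all downstream statistics are
    label-symmetric, so only labels depend on this).

    Heterozygote codes are stored as missing; the number coerced is logged
    and attached to the returned matrix as ``het_coerced``.
    """
    table = pd.read_csv(path, sep="\t", dtype=str).set_index("accession_id")
    snps = read_snp_metadata(snp_meta_path)
    acc = read_accession_metadata(accession_meta_path)

    unknown_acc = set(table.index) - set(acc["accession_id"])
    if unknown_acc:
        raise DataError(f"accession {sorted(unknown_acc)[0]!r} in genotype "
                        "table but not in accession metadata")
    unknown_snp = set(table.columns) - set(snps["snp_id"])
    if unknown_snp:
        raise DataError(f"SNP {sorted(unknown_snp)[0]!r} in genotype table "
                        "but not in SNP metadata")

    acc = acc[acc["accession_id"].isin(table.index)].reset_index(drop=True)
    snps = snps[snps["snp_id"].isin(table.columns)].reset_index(drop=True)
    table = table.loc[acc["accession_id"], snps["snp_id"]]

    raw = table.to_numpy(dtype=object)
    calls = np.full(raw.shape, MISSING, dtype=np.int8)
    het_coerced = 0
    for j in range(raw.shape[1]):
        col = raw[:, j]
        het = col == het_code
        het_coerced += int(het.sum())
        obs = col[~het & (col != missing_code) & (col != None)]  # noqa: E711
        symbols = list(dict.fromkeys(obs))  # first-observed order
        if alphabet is not None:
            extra = set(symbols) - set(alphabet)
            if extra:
                raise DataError(
                    f"non-biallelic column {table.columns[j]!r}: symbol "
                    f"{sorted(extra)[0]!r} outside alphabet {alphabet}")
            mapping = {alphabet[0]: ALLELE_A, alphabet[1]: ALLELE_B}
        else:
            if len(symbols) > 2:
                raise DataError(
                    f"non-biallelic column {table.columns[j]!r}: symbols {symbols}")
            mapping = {s: code for s, code in zip(symbols, (ALLELE_A, ALLELE_B))}
        for sym, code in mapping.items():
            calls[col == sym, j] = code
    if het_coerced:
        log.info("coerced %d heterozygous calls to missing", het_coerced)
    matrix = build_matrix(acc, snps, calls)
    matrix.het_coerced = het_coerced
    return matrix


def write_genotype_table(matrix: GenotypeMatrix, path: str | Path,
                         alphabet: tuple[str, str] = DEFAULT_ALPHABET,
                         missing_code: str = MISSING_CODE,
                         het_mask: np.ndarray | None = None,
                         het_code: str = HET_CODE) -> None:
    """Write the genotype TSV; ``het_mask`` marks missing cells to emit as
    heterozygote codes instead of no-calls (used by the simulator)."""
    symbols = np.empty(matrix.calls.shape, dtype=object)
    symbols[matrix.calls == ALLELE_A] = alphabet[0]
    symbols[matrix.calls == ALLELE_B] = alphabet[1]
    symbols[matrix.calls == MISSING] = missing_code
    if het_mask is not None:
        symbols[(matrix.calls == MISSING) & het_mask] = het_code
    out = pd.DataFrame(symbols, columns=matrix.snps["snp_id"])
    out.insert(0, "accession_id", matrix.accessions["accession_id"].to_numpy())
    out.to_csv(path, sep="\t", index=False)


def write_matrix(matrix: GenotypeMatrix, out_dir: str | Path,
                 prefix: str = "panel") -> dict[str, Path]:
    """Write genotype + both metadata TSVs; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": out_dir / f"{prefix}_genotypes.tsv",
        "snps": out_dir / f"{prefix}_snps.tsv",
        "accessions": out_dir / f"{prefix}_accessions.tsv",
    }
    write_genotype_table(matrix, paths["genotypes"])
    write_snp_metadata(matrix.snps, paths["snps"])
    write_accession_metadata(matrix.accessions, paths["accessions"])
    return paths


def read_matrix(out_dir: str | Path, prefix: str = "panel") -> GenotypeMatrix:
    out_dir = Path(out_dir)
    return read_genotype_table(out_dir / f"{prefix}_genotypes.tsv",
                               out_dir / f"{prefix}_snps.tsv",
                               out_dir / f"{prefix}_accessions.tsv")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _parse_chrom(chrom: str) -> int | None:
    c = chrom.lower().removeprefix("chr")
    try:
        return int(c)
    except ValueError:
        return None


def read_vcf(path: str | Path, accession_meta_path: str | Path) -> GenotypeMatrix:
    """Load genotypes from a VCF: 0/0 -> allele_a, 1/1 -> allele_b,
    heterozygous and no-call genotypes -> missing; multi-allelic and
    non-SNP records are skipped with a logged count."""
    acc = read_accession_metadata(accession_meta_path)
    with pysam.VariantFile(str(path)) as vcf:
        samples = [s for s in vcf.header.samples if s in set(acc["accession_id"])]
        if not samples:
            raise DataError("no VCF samples in common with accession metadata")
        rows: list[dict] = []
        cols: list[np.ndarray] = []
        skipped = 0
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                skipped += 1
                continue
            col = np.full(len(samples), MISSING, dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt == (0, 0):
                    col[i] = ALLELE_A
                elif gt == (1, 1):
                    col[i] = ALLELE_B
            rows.append({"snp_id": rec.id or f"{rec.chrom}_{rec.pos}",
                         "chromosome": _parse_chrom(rec.chrom),
                         "position_bp": rec.pos,
                         "source_panel": "other"})
            cols.append(col)
    if not rows:
        raise DataError("no usable records in VCF")
    if skipped:
        log.info("skipped %d multi-allelic/non-SNP VCF records", skipped)
    snps = pd.DataFrame(rows)
    acc = acc[acc["accession_id"].isin(samples)].reset_index(drop=True)
    order = [samples.index(a) for a in acc["accession_id"]]
    calls = np.stack(cols, axis=1)[order, :]
    matrix = build_matrix(acc, snps, calls)
    matrix.vcf_skipped = skipped
    return matrix


# ---------------------------------------------------------------------------
# BED and interval tables
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable, path: str | Path) -> None:
    """Write intervals (AnnotationInterval, ReducedRegion, or anything with
    chromosome/start_bp/end_bp and a label or n_blocks) as BED4.

    Internal 1-based inclusive spans become 0-based half-open BED lines.
    """
    with open(path, "w") as fh:
        for iv in intervals:
            label = getattr(iv, "label", None)
            if label is None:
                label = f"region_{iv.n_blocks}_blocks"
            fh.write(f"chr{iv.chromosome}\t{iv.start_bp - 1}\t{iv.end_bp}\t{label}\n")


def read_annotations_bed(path: str | Path) -> list[AnnotationInterval]:
    """Read a BED file (optionally with a 5th 'kind' column) into 1-based
    inclusive annotation intervals."""
    out: list[AnnotationInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom = _parse_chrom(parts[0])
            if chrom is None:
                raise DataError(f"unparseable BED chromosome {parts[0]!r}")
            start0, end = int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else f"{parts[0]}:{start0}-{end}"
            kind = parts[4] if len(parts) > 4 else "qtl"
            out.append(AnnotationInterval(chrom, start0 + 1, end, label, kind))
    return out


# ---------------------------------------------------------------------------
# pedigree / Q-matrix / PHYLIP
# ---------------------------------------------------------------------------

def read_pedigree(path: str | Path) -> pd.DataFrame:
    """Pedigree TSV: child, parent1, parent2, recurrent_parent (naming one of
    the parents, or empty). Missing parents are empty cells."""
    ped = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    need = {"child", "parent1", "parent2", "recurrent_parent"}
    if not need <= set(ped.columns):
        raise DataError(f"pedigree lacks columns {sorted(need - set(ped.columns))}")
    return ped


def write_pedigree(ped: pd.DataFrame, path: str | Path) -> None:
    ped.to_csv(path, sep="\t", index=False)


def read_qmatrix(path: str | Path) -> pd.DataFrame:
    """Admixture Q-matrix TSV: accession_id + one column per ancestral
    component; rows must sum to 1."""
    q = pd.read_csv(path, sep="\t", dtype={"accession_id": str})
    q = q.set_index("accession_id")
    sums = q.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        bad = sums.index[np.argmax(np.abs(sums - 1.0))]
        raise DataError(f"Q-matrix row {bad!r} sums to {sums[bad]:.6f}, not 1")
    return q


def write_qmatrix(q: pd.DataFrame, path: str | Path) -> None:
    q.reset_index().rename(columns={"index": "accession_id"}).to_csv(
        path, sep="\t", index=False)


def write_phylip_square(dist: np.ndarray, ids: Sequence[str],
                        path: str | Path) -> None:
    """Write a symmetric distance matrix in PHYLIP square format, consumable
    by external neighbor-joining tools."""
    with open(path, "w") as fh:
        fh.write(f"{len(ids)}\n")
        for i, name in enumerate(ids):
            row = " ".join(f"{dist[i, j]:.6f}" for j in range(len(ids)))
            fh.write(f"{name[:10]:<10} {row}\n")
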