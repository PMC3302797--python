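"""Core domain types for breeding-program SNP panels.

The substrate of every statistic in this package is a :class:`GenotypeMatrix`:
an accessions x SNPs table of biallelic, effectively homozygous calls.
Heterozygous calls carry no information for inbred lines and are stored as
missing; every analysis downstream can therefore treat an accession as a
single haplotype.

Calls are coded as ``int8``: 0 = allele_a, 1 = allele_b, -1 = missing.
Which allele is "a" is arbitrary -- all statistics are label-symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: call codes
ALLELE_A: int = 0
ALLELE_B: int = 1
MISSING: int = -1

#: breeding-phase groups; "foreign" accessions are carried but excluded from
#: phase comparisons
GROUPS = ("group1", "group2", "group3", "foreign")
WATER_REGIMES = ("irrigated", "non_irrigated")
SOURCE_PANELS = ("koshihikari", "eiko", "rikuu132", "other")

SNP_COLUMNS = ["snp_id", "chromosome", "position_bp", "source_panel"]
ACCESSION_COLUMNS = ["accession_id", "group", "water_regime",
                     "registration_year", "region"]


class DataError(ValueError):
    """A structural problem in input data (bad ids, non-biallelic column...)."""


@dataclass(frozen=True)
class SnpRecord:
    """One SNP of the genotyping panel.

    ``chromosome``/``position_bp`` may be ``None`` for markers that could not
    be placed on the reference pseudomolecules; such SNPs sort last and are
    removed by QC criterion 1.
    """

    snp_id: str
    chromosome: int | None
    position_bp: int | None
    source_panel: str = "other"


@dataclass(frozen=True)
class Accession:
    accession_id: str
    group: str
    water_regime: str = "irrigated"
    registration_year: int | None = None
    region: str | None = None


@dataclass(frozen=True)
class AnnotationInterval:
    """A QTL/gene/centromere interval, 1-based inclusive coordinates."""

    chromosome: int
    start_bp: int
    end_bp: int
    label: str
    kind: str = "qtl"

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise DataError(
                f"interval {self.label}: start_bp {self.start_bp} > end_bp {self.end_bp}")


def _as_nullable_int(s: pd.Series) -> pd.Series:
    return pd.to_numeric(s, errors="coerce").astype("Int64")


@dataclass
class GenotypeMatrix:
    """Accession x SNP biallelic call table with a missing-data mask.

    Attributes
    ----------
    accessions : DataFrame with columns ``accession_id, group, water_regime,
        registration_year, region`` (row order = call-matrix row order).
    snps : DataFrame with columns ``snp_id, chromosome, position_bp,
        source_panel``, sorted by (chromosome, position_bp); position-less
        SNPs sort last. Column order = call-matrix column order.
    calls : ``int8`` array, shape (n_accessions, n_snps), values in
        {0, 1, -1}.
    """

    accessions: pd.DataFrame
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.accessions = self.accessions.reset_index(drop=True)
        self.snps = self.snps.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.calls.shape != (len(self.accessions), len(self.snps)):
            raise DataError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.accessions)} accessions x {len(self.snps)} SNPs")
        bad = ~np.isin(self.calls, (ALLELE_A, ALLELE_B, MISSING))
        if bad.any():
            raise DataError("calls contain codes outside {0, 1, -1}")
        if self.snps["snp_id"].duplicated().any():
            dup = self.snps.loc[self.snps["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise DataError(f"duplicate snp_id {dup!r}")
        if self.accessions["accession_id"].duplicated().any():
            dup = self.accessions.loc[
                self.accessions["accession_id"].duplicated(), "accession_id"].iloc[0]
            raise DataError(f"duplicate accession_id {dup!r}")
        placed = self.snps.dropna(subset=["chromosome", "position_bp"])
        ties = placed.duplicated(subset=["chromosome", "position_bp"])
        if ties.any():
            row = placed.loc[ties].iloc[0]
            raise DataError(
                f"two SNPs share chromosome {row['chromosome']} position "
                f"{row['position_bp']}; tied positions are rejected")
        # sortedness of placed SNPs (positionless ones are last)
        key = placed[["chromosome", "position_bp"]].to_numpy(dtype=float)
        if len(key) and not np.all(np.diff(np.lexsort((key[:, 1], key[:, 0]))) == 1):
            raise DataError("snps not sorted by (chromosome, position_bp)")

    # -- convenience ------------------------------------------------------
    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def group_rows(self, group: str, irrigated_only: bool = True) -> np.ndarray:
        """Row indices of one breeding-phase group.

        The phase comparisons of this package follow the study design of
        excluding non-irrigated (upland) accessions, whose population
        structure differs from the irrigated pool; pass
        ``irrigated_only=False`` to keep them.
        """
        mask = (self.accessions["group"] == group).to_numpy()
        if irrigated_only:
            mask &= (self.accessions["water_regime"] == "irrigated").to_numpy()
        return np.flatnonzero(mask)

    def accession_row(self, accession_id: str) -> int:
        idx = np.flatnonzero((self.accessions["accession_id"] == accession_id).to_numpy())
        if len(idx) == 0:
            raise DataError(f"unknown accession_id {accession_id!r}")
        return int(idx[0])

    def subset_snps(self, keep: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(self.accessions.copy(),
                              self.snps.iloc[keep].reset_index(drop=True),
                              self.calls[:, keep])

    def subset_accessions(self, keep: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(self.accessions.iloc[keep].reset_index(drop=True),
                              self.snps.copy(), self.calls[keep, :])


def sort_snp_frame(snps: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Sort a SNP metadata frame by (chromosome, position); positionless last.

    Returns the sorted frame and the permutation applied (old column order ->
    new), so a call matrix can be reordered in lockstep.
    """
    snps = snps.copy()
    snps["chromosome"] = _as_nullable_int(snps["chromosome"])
    snps["position_bp"] = _as_nullable_int(snps["position_bp"])
    chrom = snps["chromosome"].astype(float).to_numpy(na_value=np.inf)
    pos = snps["position_bp"].astype(float).to_numpy(na_value=np.inf)
    order = np.lexsort((pos, chrom))
    return snps.iloc[order].reset_index(drop=True), order


def build_matrix(accessions: pd.DataFrame, snps: pd.DataFrame,
                 calls: np.ndarray) -> GenotypeMatrix:
    """Assemble a GenotypeMatrix, sorting SNPs by genome position."""
    snps_sorted, order = sort_snp_frame(snps)
    return GenotypeMatrix(accessions, snps_sorted, np.asarray(calls)[:, order])


def check_biallelic(matrix: GenotypeMatrix) -> None:
    """Assert the loaded-matrix invariant: every column is missing-or-biallelic."""
    if not np.isin(matrix.calls, (ALLELE_A, ALLELE_B, MISSING)).all():
        raise DataError("matrix contains non-biallelic codes")
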