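"""Informative-SNP quality control.

A SNP is non-informative if (1) it has no genome position, (2) heterozygous
or no-signal calls exceed 50% of accessions, or (3) its minor-allele
frequency among non-missing calls is at or below 2%. Criterion order 1->2->3
labels the disposition of each removed SNP; membership of the retained panel
does not depend on the order. Thresholds are parameters with these defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import MISSING, DataError, GenotypeMatrix

DISPOSITIONS = ("informative", "no_position", "missing_excess", "rare_allele")


@dataclass
class QcReport:
    n_input: int
    n_removed_no_position: int
    n_removed_missing_het: int
    n_removed_rare: int
    n_informative: int
    dispositions: pd.DataFrame  # snp_id, disposition

    def __post_init__(self) -> None:
        total = (self.n_informative + self.n_removed_no_position
                 + self.n_removed_missing_het + self.n_removed_rare)
        assert total == self.n_input, "QC dispositions do not partition the panel"

    def summary(self) -> str:
        return (f"{self.n_input} SNPs in: {self.n_removed_no_position} unplaced, "
                f"{self.n_removed_missing_het} >max missing/het, "
                f"{self.n_removed_rare} rare-allele; "
                f"{self.n_informative} informative SNPs retained")


def filter_informative(matrix: GenotypeMatrix,
                       max_missing_fraction: float = 0.5,
                       min_allele_freq: float = 0.02,
                       ) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the three non-informative criteria and return the filtered panel.

    Criterion 2 is a strict inequality (missing fraction > threshold removes,
    exactly at the threshold retains); criterion 3 is inclusive (MAF <=
    threshold removes), computed over non-missing calls only. Monomorphic
    SNPs have MAF 0 and fall under criterion 3.
    """
    calls = matrix.calls
    n_acc = matrix.n_accessions
    no_pos = (matrix.snps["chromosome"].isna()
              | matrix.snps["position_bp"].isna()).to_numpy()
    missing_frac = (calls == MISSING).sum(axis=0) / n_acc
    n_nonmissing = (calls != MISSING).sum(axis=0)
    n_b = (calls == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_b = np.where(n_nonmissing > 0, n_b / n_nonmissing, 0.0)
    maf = np.minimum(freq_b, 1.0 - freq_b)

    disposition = np.full(matrix.n_snps, "informative", dtype=object)
    disposition[(disposition == "informative") & no_pos] = "no_position"
    disposition[(disposition == "informative")
                & (missing_frac > max_missing_fraction)] = "missing_excess"
    disposition[(disposition == "informative")
                & (maf <= min_allele_freq)] = "rare_allele"

    keep = np.flatnonzero(disposition == "informative")
    if len(keep) == 0:
        raise DataError("empty panel: every SNP removed by QC")
    report = QcReport(
        n_input=matrix.n_snps,
        n_removed_no_position=int((disposition == "no_position").sum()),
        n_removed_missing_het=int((disposition == "missing_excess").sum()),
        n_removed_rare=int((disposition == "rare_allele").sum()),
        n_informative=len(keep),
        dispositions=pd.DataFrame({"snp_id": matrix.snps["snp_id"],
                                   "disposition": disposition}),
    )
    return matrix.subset_snps(keep), report
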