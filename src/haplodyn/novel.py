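"""Novel polymorphisms: alleles and block haplotypes absent from the founder
group, and their accrual over registration years.

A novel SNP is monomorphic among the reference (founder-phase) group's
non-missing calls, with the alternate allele observed in a later group. A
cultivar's novel-block count is the number of windows where its complete
five-call string does not occur among the reference group's complete
strings. Regressing that count on registration year gives the per-year
accrual rate of new haplotype polymorphisms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import MISSING, DataError, GenotypeMatrix
from .blocks import HaplotypeBlock, window_codes

log = logging.getLogger(__name__)


def find_novel_snps(matrix: GenotypeMatrix,
                    reference_group: str = "group1",
                    later_groups: tuple[str, ...] = ("group2", "group3"),
                    irrigated_only: bool = True) -> pd.DataFrame:
    """SNPs monomorphic in the reference group whose other allele appears in
    any later group (union reading; per-group frequencies are reported so a
    both-groups filter can be applied downstream).

    Returns columns: snp_id, novel_allele (call code), plus
    ``freq_<group>`` novel-allele frequencies over non-missing calls.
    SNPs with zero non-missing reference calls are skipped with a logged
    count.
    """
    ref_rows = matrix.group_rows(reference_group, irrigated_only)
    later_rows = {g: matrix.group_rows(g, irrigated_only) for g in later_groups}
    ref = matrix.calls[ref_rows, :]
    rows = []
    skipped = 0
    for j in range(matrix.n_snps):
        col = ref[:, j]
        obs = col[col != MISSING]
        if obs.size == 0:
            skipped += 1
            continue
        if np.unique(obs).size != 1:
            continue
        novel = 1 - int(obs[0])
        freqs = {}
        seen = False
        for g, rows_g in later_rows.items():
            gcol = matrix.calls[rows_g, j]
            gobs = gcol[gcol != MISSING]
            f = float((gobs == novel).mean()) if gobs.size else 0.0
            freqs[f"freq_{g}"] = f
            seen = seen or (gobs == novel).any()
        if seen:
            rows.append({"snp_id": matrix.snps["snp_id"].iloc[j],
                         "novel_allele": novel, **freqs})
    if skipped:
        log.info("skipped %d SNPs with no non-missing reference call", skipped)
    cols = ["snp_id", "novel_allele"] + [f"freq_{g}" for g in later_groups]
    return pd.DataFrame(rows, columns=cols)


def count_novel_block_haplotypes(matrix: GenotypeMatrix,
                                 blocks: list[HaplotypeBlock],
                                 reference_rows: np.ndarray,
                                 cultivar_row: int) -> int:
    """Number of blocks where the cultivar carries a complete haplotype
    string absent from the reference group's complete strings.

    Blocks where the cultivar has a missing call contribute 0; blocks where
    the reference group has no complete string are skipped (logged).
    """
    count = 0
    skipped = 0
    for block in blocks:
        codes, complete = window_codes(matrix.calls, block.snp_cols)
        ref_codes = codes[reference_rows][complete[reference_rows]]
        if ref_codes.size == 0:
            skipped += 1
            continue
        if complete[cultivar_row] and codes[cultivar_row] not in set(ref_codes.tolist()):
            count += 1
    if skipped:
        log.debug("skipped %d blocks with empty reference census", skipped)
    return count


def novel_block_counts(matrix: GenotypeMatrix,
                       blocks: list[HaplotypeBlock],
                       reference_group: str = "group1",
                       cultivar_groups: tuple[str, ...] = ("group2", "group3"),
                       irrigated_only: bool = True) -> pd.DataFrame:
    """Per-cultivar novel-block counts with registration years, vectorized
    over blocks. Cultivars in the reference group are excluded."""
    ref_rows = matrix.group_rows(reference_group, irrigated_only)
    cult_rows = np.concatenate(
        [matrix.group_rows(g, irrigated_only) for g in cultivar_groups])
    counts = np.zeros(len(cult_rows), dtype=int)
    for block in blocks:
        codes, complete = window_codes(matrix.calls, block.snp_cols)
        ref_codes = np.unique(codes[ref_rows][complete[ref_rows]])
        if ref_codes.size == 0:
            continue
        cc = codes[cult_rows]
        novel = complete[cult_rows] & ~np.isin(cc, ref_codes)
        counts += novel
    acc = matrix.accessions.iloc[cult_rows]
    return pd.DataFrame({
        "accession_id": acc["accession_id"].to_numpy(),
        "group": acc["group"].to_numpy(),
        "registration_year": acc["registration_year"].to_numpy(dtype=float),
        "novel_block_count": counts,
    })


@dataclass(frozen=True)
class AccrualRegression:
    slope: float       # new polymorphisms per year
    intercept: float
    r_squared: float
    p_value: float
    stderr: float
    n_cultivars: int


def fit_accrual(counts: pd.DataFrame) -> AccrualRegression:
    """OLS of novel-block count on registration year (y = a + b x + e) with
    the classical two-sided t-test on the slope."""
    df = counts.dropna(subset=["registration_year", "novel_block_count"])
    if len(df) < 3:
        raise DataError("need >= 3 cultivars with registration years for a fit")
    x = df["registration_year"].to_numpy(dtype=float)
    y = df["novel_block_count"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise DataError("degenerate design: all registration years identical")
    if np.ptp(y) == 0:
        return AccrualRegression(0.0, float(y[0]), 0.0, 1.0, 0.0, len(df))
    res = stats.linregress(x, y)
    return AccrualRegression(slope=float(res.slope),
                             intercept=float(res.intercept),
                             r_squared=float(res.rvalue ** 2),
                             p_value=float(res.pvalue),
                             stderr=float(res.stderr),
                             n_cultivars=len(df))


def plot_accrual(counts: pd.DataFrame, fit: AccrualRegression, path) -> None:
    """Diagnostic scatter of per-cultivar novel counts vs year with the OLS line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(counts["registration_year"], counts["novel_block_count"],
               s=12, alpha=0.7)
    xs = np.linspace(counts["registration_year"].min(),
                     counts["registration_year"].max(), 10)
    ax.plot(xs, fit.intercept + fit.slope * xs, color="C3",
            label=f"slope {fit.slope:.2f}/yr, $R^2$={fit.r_squared:.2f}")
    ax.set_xlabel("registration year")
    ax.set_ylabel("new haplotype polymorphisms")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
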