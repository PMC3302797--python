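"""Five-SNP sliding-window haplotype blocks and per-group diversity indices.

A haplotype block is a window of ``window`` (default 5) consecutive
same-chromosome SNPs, stepped by one SNP, so a chromosome carrying ``n_c``
mapped SNPs yields ``max(0, n_c - window + 1)`` blocks. A block's "alleles"
are the distinct call strings over its SNPs among accessions with no missing
call in the window, and the diversity index of a block within a group is

    (number of distinct haplotype strings in the group) / (group size).

Accessions with a missing call in the window are excluded from the distinct
count but stay in the denominator (the group size); a complete-case
denominator is available via ``denominator="complete"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import MISSING, DataError, GenotypeMatrix

DEFAULT_WINDOW = 5


@dataclass(frozen=True)
class HaplotypeBlock:
    block_id: int
    chromosome: int
    snp_ids: tuple[str, ...]
    snp_cols: tuple[int, ...]  # column indices into the matrix
    start_bp: int
    end_bp: int


@dataclass(frozen=True)
class BlockCensus:
    block_id: int
    group: str
    n_distinct_haplotypes: int
    n_group: int
    n_complete: int
    diversity_index: float


def enumerate_blocks(snps: pd.DataFrame,
                     window: int = DEFAULT_WINDOW) -> list[HaplotypeBlock]:
    """Enumerate sliding windows of ``window`` consecutive SNPs per chromosome.

    ``snps`` must be a position-sorted SNP frame (as held by a
    GenotypeMatrix); unplaced SNPs are ignored. Chromosomes with fewer than
    ``window`` SNPs contribute no blocks. Block ids are genome-wide and
    ordered, so consecutive ids on one chromosome are overlapping windows
    sharing ``window - 1`` SNPs.
    """
    if window < 2:
        raise DataError("window must be >= 2")
    blocks: list[HaplotypeBlock] = []
    placed = snps.dropna(subset=["chromosome", "position_bp"])
    bid = 0
    for chrom, sub in placed.groupby("chromosome", sort=True):
        cols = sub.index.to_numpy()
        pos = sub["position_bp"].to_numpy(dtype=np.int64)
        for s in range(0, len(cols) - window + 1):
            sel = cols[s:s + window]
            blocks.append(HaplotypeBlock(
                block_id=bid,
                chromosome=int(chrom),
                snp_ids=tuple(snps["snp_id"].iloc[sel]),
                snp_cols=tuple(int(c) for c in sel),
                start_bp=int(pos[s]),
                end_bp=int(pos[s + window - 1]),
            ))
            bid += 1
    return blocks


def expected_block_count(snps_per_chromosome: Iterable[int],
                         window: int = DEFAULT_WINDOW) -> int:
    """Closed-form block total: sum over chromosomes of max(0, n_c - w + 1)."""
    return sum(max(0, int(n) - window + 1) for n in snps_per_chromosome)


def mean_window_span_kb(genome_bp: float, n_snps: int,
                        window: int = DEFAULT_WINDOW) -> float:
    """Density-based mean window size: window x (genome length / SNP count),
    in kb — e.g. 5 x (380 Mb / 3259) ~= 583 kb."""
    return window * (genome_bp / n_snps) / 1000.0


def window_codes(calls: np.ndarray, snp_cols: Sequence[int]
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Encode each accession's window string as an integer; returns
    (codes, complete_mask). Codes are only meaningful where complete."""
    sub = calls[:, list(snp_cols)]
    complete = (sub != MISSING).all(axis=1)
    weights = 1 << np.arange(sub.shape[1], dtype=np.int64)
    codes = (np.where(sub == 1, 1, 0).astype(np.int64) @ weights)
    return codes, complete


def census_block(matrix: GenotypeMatrix, block: HaplotypeBlock,
                 group_rows: np.ndarray, group: str = "",
                 denominator: str = "group") -> BlockCensus:
    """Census one block within one group of accessions (row indices)."""
    if len(group_rows) == 0:
        raise DataError("group size 0")
    codes, complete = window_codes(matrix.calls, block.snp_cols)
    gc = complete[group_rows]
    n_complete = int(gc.sum())
    n_distinct = int(np.unique(codes[group_rows][gc]).size)
    denom = n_complete if denominator == "complete" else len(group_rows)
    index = n_distinct / denom if denom else float("nan")
    return BlockCensus(block.block_id, group, n_distinct, len(group_rows),
                       n_complete, index)


def census_all(matrix: GenotypeMatrix, groups: dict[str, np.ndarray],
               blocks: Sequence[HaplotypeBlock] | None = None,
               denominator: str = "group") -> pd.DataFrame:
    """Census every block x group; returns a tidy table ordered by
    (block_id, group insertion order)."""
    if blocks is None:
        blocks = enumerate_blocks(matrix.snps)
    rows = []
    for block in blocks:
        codes, complete = window_codes(matrix.calls, block.snp_cols)
        for group, gidx in groups.items():
            if len(gidx) == 0:
                raise DataError(f"group {group!r} is empty")
            gc = complete[gidx]
            n_complete = int(gc.sum())
            n_distinct = int(np.unique(codes[gidx][gc]).size)
            denom = n_complete if denominator == "complete" else len(gidx)
            rows.append((block.block_id, group, n_distinct, len(gidx),
                         n_complete,
                         n_distinct / denom if denom else float("nan")))
    return pd.DataFrame(rows, columns=["block_id", "group",
                                       "n_distinct_haplotypes", "n_group",
                                       "n_complete", "diversity_index"])


def segregating_sites_block(matrix: GenotypeMatrix, block: HaplotypeBlock,
                            group_rows: np.ndarray) -> int:
    """Alternative per-block polymorphism counter: number of SNP sites in the
    window segregating within the group (not the default reading of block
    polymorphism, provided for comparison)."""
    sub = matrix.calls[np.ix_(group_rows, list(block.snp_cols))]
    seg = 0
    for j in range(sub.shape[1]):
        col = sub[:, j][sub[:, j] != MISSING]
        if col.size and np.unique(col).size > 1:
            seg += 1
    return seg


def blocks_frame(blocks: Sequence[HaplotypeBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        {"block_id": [b.block_id for b in blocks],
         "chromosome": [b.chromosome for b in blocks],
         "start_bp": [b.start_bp for b in blocks],
         "end_bp": [b.end_bp for b in blocks],
         "snp_ids": ["|".join(b.snp_ids) for b in blocks]})
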