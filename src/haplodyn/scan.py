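"""Cross-group diversity comparison and reduced-diversity region scanning.

Artificial selection during a breeding program collapses haplotype diversity
locally: blocks in which both later breeding-phase groups hold fewer than
half (strictly) of the founder group's distinct haplotypes are flagged, and
maximal runs of consecutive flagged windows are merged into genomic regions.
Regions are then overlapped with QTL/gene/centromere annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import AnnotationInterval, DataError
from .blocks import HaplotypeBlock


@dataclass(frozen=True)
class GroupComparison:
    group_pair: tuple[str, str]
    n_blocks_higher_in_first: int
    n_blocks_higher_in_second: int
    n_ties: int
    mannwhitney_p: float

    @property
    def n_blocks(self) -> int:
        return (self.n_blocks_higher_in_first + self.n_blocks_higher_in_second
                + self.n_ties)


@dataclass
class ReducedRegion:
    chromosome: int
    start_bp: int
    end_bp: int
    n_blocks: int
    block_ids: tuple[int, ...]
    annotations: list[str] = field(default_factory=list)

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp) / 1000.0


def compare_groups(census_a: pd.DataFrame, census_b: pd.DataFrame,
                   ) -> GroupComparison:
    """Block-wise higher/lower/tie counts on the diversity index, plus a
    two-sided Mann-Whitney test on the two index distributions."""
    a = census_a.sort_values("block_id").reset_index(drop=True)
    b = census_b.sort_values("block_id").reset_index(drop=True)
    if not np.array_equal(a["block_id"].to_numpy(), b["block_id"].to_numpy()):
        raise DataError("censuses cover different block sets")
    ia = a["diversity_index"].to_numpy()
    ib = b["diversity_index"].to_numpy()
    higher_a = int((ia > ib).sum())
    higher_b = int((ib > ia).sum())
    ties = int((ia == ib).sum())
    if np.array_equal(ia, ib):
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(ia, ib, alternative="two-sided").pvalue)
    ga = a["group"].iloc[0] if "group" in a else "a"
    gb = b["group"].iloc[0] if "group" in b else "b"
    return GroupComparison((ga, gb), higher_a, higher_b, ties, p)


def flag_reduced_blocks(census_g1: pd.DataFrame, census_g2: pd.DataFrame,
                        census_g3: pd.DataFrame, ratio: float = 0.5,
                        on: str = "counts",
                        include_zero_reference: bool = False) -> list[int]:
    """Block ids where both later groups fall strictly below ``ratio`` x the
    reference group's polymorphism level.

    ``on="counts"`` (default) applies the rule to raw distinct-haplotype
    counts — group sizes differ, and the selection rule concerns the number
    of polymorphisms, not the normalized index; ``on="index"`` uses the
    diversity index instead. Blocks where the reference count is 0 (or any
    group is entirely missing) are excluded unless ``include_zero_reference``.
    """
    col = "n_distinct_haplotypes" if on == "counts" else "diversity_index"
    frames = []
    for c in (census_g1, census_g2, census_g3):
        frames.append(c.sort_values("block_id").reset_index(drop=True))
    ids = frames[0]["block_id"].to_numpy()
    for f in frames[1:]:
        if not np.array_equal(f["block_id"].to_numpy(), ids):
            raise DataError("censuses cover different block sets")
    n1, n2, n3 = (f[col].to_numpy(dtype=float) for f in frames)
    flagged = (n2 < ratio * n1) & (n3 < ratio * n1)
    if not include_zero_reference:
        informative = (frames[0]["n_distinct_haplotypes"].to_numpy() > 0) \
            & (frames[1]["n_complete"].to_numpy() > 0) \
            & (frames[2]["n_complete"].to_numpy() > 0)
        flagged &= informative
    return [int(i) for i in ids[flagged]]


def merge_regions(flagged_ids: Sequence[int],
                  blocks: Sequence[HaplotypeBlock],
                  min_blocks: int = 2) -> list[ReducedRegion]:
    """Merge maximal runs of consecutive flagged windows into regions.

    Adjacency is consecutive window index on one chromosome (blocks sharing
    window-1 SNPs); no base-pair gap tolerance is applied. Runs shorter than
    ``min_blocks`` are dropped (every reported selection region comprises at
    least two windows by default; pass 1 to keep singletons).
    """
    by_id = {b.block_id: b for b in blocks}
    unknown = set(flagged_ids) - set(by_id)
    if unknown:
        raise DataError(f"flagged block id {sorted(unknown)[0]} not in block table")
    ids = sorted(set(int(i) for i in flagged_ids))
    regions: list[ReducedRegion] = []
    run: list[int] = []

    def close(run: list[int]) -> None:
        if len(run) >= min_blocks:
            first, last = by_id[run[0]], by_id[run[-1]]
            regions.append(ReducedRegion(first.chromosome, first.start_bp,
                                         last.end_bp, len(run), tuple(run)))

    for i in ids:
        if run and (i == run[-1] + 1
                    and by_id[i].chromosome == by_id[run[-1]].chromosome):
            run.append(i)
        else:
            if run:
                close(run)
            run = [i]
    if run:
        close(run)
    return regions


def annotate_regions(regions: Sequence[ReducedRegion],
                     annotations: Sequence[AnnotationInterval],
                     ) -> tuple[list[ReducedRegion], int]:
    """Attach overlapping annotation labels to each region.

    An annotation co-localizes with a region iff their closed 1-based
    intervals share at least one base pair on the same chromosome. Returns
    the regions (labels filled in) and the total QTL co-localization count
    with redundancy (an annotation overlapping two regions counts twice).
    """
    total = 0
    for region in regions:
        labels = []
        for ann in annotations:
            if (ann.chromosome == region.chromosome
                    and ann.start_bp <= region.end_bp
                    and ann.end_bp >= region.start_bp):
                labels.append(ann.label)
                if ann.kind == "qtl":
                    total += 1
        region.annotations = labels
    return list(regions), total


def regions_frame(regions: Sequence[ReducedRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {"chromosome": [r.chromosome for r in regions],
         "start_bp": [r.start_bp for r in regions],
         "end_bp": [r.end_bp for r in regions],
         "length_kb": [r.length_kb for r in regions],
         "n_blocks": [r.n_blocks for r in regions],
         "block_ids": ["|".join(map(str, r.block_ids)) for r in regions],
         "annotations": ["|".join(r.annotations) for r in regions]})
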