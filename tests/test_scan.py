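"""Diversity comparisons, reduced-block flagging, region merging, overlap."""

import numpy as np
import pandas as pd
import pytest

from haplodyn.blocks import enumerate_blocks
from haplodyn.model import AnnotationInterval, DataError
from haplodyn.scan import (annotate_regions, compare_groups,
                           flag_reduced_blocks, merge_regions)

from conftest import mk_matrix


def census(block_ids, n_distinct, group="g", n_group=10, n_complete=None):
    n_complete = n_complete if n_complete is not None else [n_group] * len(block_ids)
    return pd.DataFrame({
        "block_id": block_ids, "group": group,
        "n_distinct_haplotypes": n_distinct, "n_group": n_group,
        "n_complete": n_complete,
        "diversity_index": np.asarray(n_distinct) / n_group})


def test_identical_censuses_all_ties():
    a = census([0, 1, 2], [3, 4, 5], "g1")
    b = census([0, 1, 2], [3, 4, 5], "g2")
    c = compare_groups(a, b)
    assert c.n_ties == 3 and c.n_blocks_higher_in_first == 0
    assert c.mannwhitney_p == pytest.approx(1.0)


def test_three_block_exact_mannwhitney():
    a = census([0, 1, 2], [9, 8, 7], "g1")
    b = census([0, 1, 2], [1, 2, 3], "g2")
    c = compare_groups(a, b)
    assert c.n_blocks_higher_in_first == 3
    # complete separation of two samples of 3: exact two-sided p = 2/20
    assert c.mannwhitney_p == pytest.approx(0.1)


def test_mismatched_block_sets_rejected():
    with pytest.raises(DataError):
        compare_groups(census([0, 1], [1, 1]), census([0, 2], [1, 1]))


def test_flag_rule_strict_conjunction():
    g1 = census([0, 1], [4, 4], "g1")
    g2 = census([0, 1], [1, 2], "g2")
    g3 = census([0, 1], [1, 1], "g3")
    flagged = flag_reduced_blocks(g1, g2, g3)
    assert flagged == [0]  # block 1 fails: 2 is not < 2


def test_flag_zero_reference_excluded_by_default():
    g1 = census([0], [1], "g1")
    g2 = census([0], [0], "g2", n_complete=[0])   # all-missing group
    g3 = census([0], [0], "g3", n_complete=[0])
    assert flag_reduced_blocks(g1, g2, g3) == []
    assert flag_reduced_blocks(g1, g2, g3, include_zero_reference=True) == [0]


def test_flag_ratio_limits():
    g1 = census([0, 1], [4, 4], "g1")
    g2 = census([0, 1], [3, 1], "g2")
    g3 = census([0, 1], [2, 1], "g3")
    assert flag_reduced_blocks(g1, g2, g3, ratio=1.0) == [0, 1]
    assert flag_reduced_blocks(g1, g2, g3, ratio=1e-9) == []


def blocks_for(n_snps, chromosome=1, start=100_000, step=31_000):
    m = mk_matrix(np.zeros((2, n_snps), dtype=np.int8),
                  chromosome=[chromosome] * n_snps,
                  position=[start + i * step for i in range(n_snps)])
    return enumerate_blocks(m.snps)


def test_merge_adjacent_flagged_blocks():
    blocks = blocks_for(10)
    regions = merge_regions([2, 3], blocks)
    assert len(regions) == 1
    assert regions[0].n_blocks == 2
    assert regions[0].start_bp == blocks[2].start_bp
    assert regions[0].end_bp == blocks[3].end_bp


def test_singleton_flagged_block_dropped_by_default():
    blocks = blocks_for(10)
    assert merge_regions([2], blocks) == []
    assert len(merge_regions([2], blocks, min_blocks=1)) == 1


def test_region_length_kb():
    # 6 SNPs spaced 12,400 bp: two windows spanning 100,000-162,000 = 62 kb
    m = mk_matrix(np.zeros((2, 6), dtype=np.int8),
                  position=[100_000 + i * 12_400 for i in range(6)])
    blocks = enumerate_blocks(m.snps)
    region = merge_regions([0, 1], blocks)[0]
    assert (region.start_bp, region.end_bp) == (100_000, 162_000)
    assert region.length_kb == pytest.approx(62.0)


def brute_force_runs(flagged, blocks, min_blocks):
    """Oracle: group flagged ids by scanning every block in order."""
    flagged = set(flagged)
    runs, current = [], []
    by_id = {b.block_id: b for b in blocks}
    for b in blocks:
        if b.block_id in flagged and (
                not current
                or (b.block_id == current[-1] + 1
                    and b.chromosome == by_id[current[-1]].chromosome)):
            current.append(b.block_id)
        else:
            if current:
                runs.append(current)
            current = [b.block_id] if b.block_id in flagged else []
    if current:
        runs.append(current)
    return [tuple(r) for r in runs if len(r) >= min_blocks]


def test_merge_matches_brute_force_runs():
    rng = np.random.default_rng(5)
    m = mk_matrix(np.zeros((2, 40), dtype=np.int8),
                  chromosome=[1] * 25 + [2] * 15,
                  position=[100_000 * (i + 1) for i in range(25)]
                  + [100_000 * (i + 1) for i in range(15)])
    blocks = enumerate_blocks(m.snps)
    ids = [b.block_id for b in blocks]
    for _ in range(30):
        flagged = [i for i in ids if rng.random() < 0.4]
        for mb in (1, 2, 3):
            got = [r.block_ids for r in merge_regions(flagged, blocks, mb)]
            assert got == brute_force_runs(flagged, blocks, mb)


def test_merge_idempotent_partition():
    blocks = blocks_for(20)
    flagged = [0, 1, 2, 5, 6, 10]
    regions = merge_regions(flagged, blocks, min_blocks=1)
    covered = [i for r in regions for i in r.block_ids]
    assert sorted(covered) == sorted(flagged)  # every flagged block in one run


def test_annotation_overlap_closed_intervals():
    blocks = blocks_for(10, chromosome=11, start=11_600_000, step=750_000)
    region = merge_regions([0, 1], blocks)[0]  # ~11.6-15.35 Mb
    centromere = AnnotationInterval(11, 12_200_000, 14_200_000,
                                    "centromere_11", "centromere")
    wrong_chrom = AnnotationInterval(3, 12_200_000, 14_200_000, "c3", "qtl")
    touching = AnnotationInterval(11, 11_000_000, region.start_bp, "edge", "qtl")
    regions, n_qtl = annotate_regions([region],
                                      [centromere, wrong_chrom, touching])
    assert "centromere_11" in regions[0].annotations
    assert "c3" not in regions[0].annotations
    assert "edge" in regions[0].annotations  # shared single bp counts
    assert n_qtl == 1


def test_annotate_empty_set():
    blocks = blocks_for(10)
    region = merge_regions([0, 1], blocks)[0]
    regions, n_qtl = annotate_regions([region], [])
    assert regions[0].annotations == [] and n_qtl == 0
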