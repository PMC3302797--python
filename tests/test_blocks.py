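"""Sliding-window block enumeration and the distinct-haplotype census."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import haplodyn as hd
from haplodyn.blocks import (census_all, census_block, enumerate_blocks,
                             expected_block_count, window_codes)
from haplodyn.model import MISSING, DataError

from conftest import mk_matrix


def layout_matrix(snps_per_chromosome, n_acc=3, seed=0):
    rng = np.random.default_rng(seed)
    chrom, pos = [], []
    for c, n in enumerate(snps_per_chromosome):
        chrom += [c + 1] * n
        pos += sorted(rng.choice(np.arange(1, 10_000_000), n,
                                 replace=False).tolist())
    calls = rng.integers(0, 2, size=(n_acc, len(chrom))).astype(np.int8)
    return mk_matrix(calls, chromosome=chrom, position=pos)


@given(st.lists(st.integers(min_value=0, max_value=40), min_size=1,
                max_size=15))
@settings(max_examples=60, deadline=None)
def test_window_count_identity(layout):
    """Total blocks equal the sum over chromosomes of max(0, n_c - 4)."""
    layout = [n for n in layout]
    if sum(layout) == 0:
        layout[0] = 1
    m = layout_matrix(layout)
    blocks = enumerate_blocks(m.snps)
    assert len(blocks) == expected_block_count(layout)


@pytest.mark.parametrize("n,expected", [(5, 1), (4, 0), (6, 2)])
def test_single_chromosome_boundaries(n, expected):
    m = layout_matrix([n])
    assert len(enumerate_blocks(m.snps)) == expected


def test_consecutive_blocks_share_four_snps():
    m = layout_matrix([8, 7])
    blocks = enumerate_blocks(m.snps)
    for a, b in zip(blocks, blocks[1:]):
        if a.chromosome == b.chromosome:
            assert len(set(a.snp_ids) & set(b.snp_ids)) == 4


def test_census_distinct_strings():
    # strings AAAAA, AAAAA, ABABA, BBBBB -> 3 distinct, index 3/4
    calls = np.array([[0, 0, 0, 0, 0],
                      [0, 0, 0, 0, 0],
                      [0, 1, 0, 1, 0],
                      [1, 1, 1, 1, 1]], dtype=np.int8)
    m = mk_matrix(calls)
    block = enumerate_blocks(m.snps)[0]
    c = census_block(m, block, np.arange(4), "g")
    assert c.n_distinct_haplotypes == 3
    assert c.diversity_index == pytest.approx(0.75)


def test_census_monomorphic_minimum():
    calls = np.zeros((6, 5), dtype=np.int8)
    m = mk_matrix(calls)
    block = enumerate_blocks(m.snps)[0]
    c = census_block(m, block, np.arange(6), "g")
    assert c.n_distinct_haplotypes == 1
    assert c.diversity_index == pytest.approx(1 / 6)


def test_missing_call_excluded_from_count_but_kept_in_denominator():
    calls = np.zeros((41, 5), dtype=np.int8)
    calls[0, 2] = MISSING
    m = mk_matrix(calls)
    block = enumerate_blocks(m.snps)[0]
    c = census_block(m, block, np.arange(41), "g1")
    assert c.n_distinct_haplotypes == 1
    assert c.n_complete == 40
    assert c.diversity_index == pytest.approx(1 / 41)


def test_complete_case_denominator_option():
    calls = np.zeros((4, 5), dtype=np.int8)
    calls[0, 0] = MISSING
    m = mk_matrix(calls)
    block = enumerate_blocks(m.snps)[0]
    c = census_block(m, block, np.arange(4), "g", denominator="complete")
    assert c.diversity_index == pytest.approx(1 / 3)


def test_allele_relabeling_leaves_counts_unchanged(toy_panel):
    matrix, _ = toy_panel
    blocks = enumerate_blocks(matrix.snps)
    groups = {"group1": matrix.group_rows("group1")}
    before = census_all(matrix, groups, blocks)
    flipped = matrix.calls.copy()
    rng = np.random.default_rng(0)
    for j in rng.choice(matrix.n_snps, 5, replace=False):
        nm = flipped[:, j] != MISSING
        flipped[nm, j] = 1 - flipped[nm, j]
    from haplodyn.model import GenotypeMatrix
    m2 = GenotypeMatrix(matrix.accessions, matrix.snps, flipped)
    after = census_all(m2, groups, blocks)
    assert before["n_distinct_haplotypes"].tolist() == \
        after["n_distinct_haplotypes"].tolist()


def test_duplicate_accession_never_increases_distinct_count():
    rng = np.random.default_rng(2)
    calls = rng.choice([0, 1, MISSING], p=[0.45, 0.45, 0.1],
                       size=(10, 5)).astype(np.int8)
    m = mk_matrix(calls)
    block = enumerate_blocks(m.snps)[0]
    base = census_block(m, block, np.arange(10), "g").n_distinct_haplotypes
    dup = np.vstack([calls, calls[3:4]])
    m2 = mk_matrix(dup)
    block2 = enumerate_blocks(m2.snps)[0]
    extended = census_block(m2, block2, np.arange(11), "g").n_distinct_haplotypes
    assert extended == base


def brute_force_census(calls, rows, cols):
    """Independent oracle: distinct complete call strings as python tuples."""
    seen = set()
    for r in rows:
        s = tuple(int(calls[r, c]) for c in cols)
        if all(v != MISSING for v in s):
            seen.add(s)
    return len(seen)


def test_census_matches_brute_force_oracle():
    rng = np.random.default_rng(7)
    for _ in range(5):
        calls = rng.choice([0, 1, MISSING], p=[0.4, 0.4, 0.2],
                           size=(20, 50)).astype(np.int8)
        m = mk_matrix(calls)
        blocks = enumerate_blocks(m.snps)
        for block in blocks:
            c = census_block(m, block, np.arange(20), "g")
            assert c.n_distinct_haplotypes == brute_force_census(
                calls, range(20), block.snp_cols)


def test_census_all_cardinality_and_determinism(toy_panel):
    matrix, _ = toy_panel
    blocks = enumerate_blocks(matrix.snps)
    groups = {g: matrix.group_rows(g) for g in ("group1", "group2", "group3")}
    t1 = census_all(matrix, groups, blocks)
    t2 = census_all(matrix, groups, blocks)
    assert len(t1) == len(blocks) * 3
    assert t1.equals(t2)


def test_empty_group_rejected():
    m = mk_matrix(np.zeros((3, 5), dtype=np.int8))
    block = enumerate_blocks(m.snps)[0]
    with pytest.raises(DataError):
        census_block(m, block, np.array([], dtype=int), "g")
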