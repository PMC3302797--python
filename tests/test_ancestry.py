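"""Pedigree founder counting, admixture classification, group statistics,
simple-matching distances."""

import numpy as np
import pandas as pd
import pytest

from haplodyn.ancestry import (PedigreeGraph, classify_admixed,
                               founder_frequencies, group_component_stats,
                               simple_matching_distance, top_founder_share)
from haplodyn.model import MISSING, DataError

from conftest import mk_matrix


def graph(rows):
    return PedigreeGraph.from_frame(pd.DataFrame(
        rows, columns=["child", "parent1", "parent2", "recurrent_parent"]))


def test_single_cross_half_shares():
    g = graph([("C", "F1", "F2", "")])
    f = founder_frequencies(g, ["C"])
    shares = dict(zip(f["founder"], f["share"]))
    assert shares == {"F1": 0.5, "F2": 0.5}


def test_backcross_skips_recurrent_subtree():
    # H = F1 x F2; C = H x F1 with F1 the recurrent parent: only the path
    # through H is counted -> occurrences {F1: 1, F2: 1}
    g = graph([("H", "F1", "F2", ""), ("C", "H", "F1", "F1")])
    occ = g.founder_occurrences("C")
    assert dict(occ) == {"F1": 1, "F2": 1}


def test_path_occurrences_counted_per_path():
    # F1 reached via both parents counts twice
    g = graph([("A", "F1", "F2", ""), ("B", "F1", "F3", ""),
               ("C", "A", "B", "")])
    occ = g.founder_occurrences("C")
    assert occ["F1"] == 2
    f = founder_frequencies(g, ["C"])
    assert f["share"].sum() == pytest.approx(1.0)
    u = founder_frequencies(g, ["C"], unique_ancestors=True)
    assert dict(zip(u["founder"], u["occurrences"]))["F1"] == 1


def test_cycle_rejected_with_member_named():
    with pytest.raises(DataError, match="cycle"):
        graph([("A", "B", "X", ""), ("B", "A", "Y", "")])


def test_top_founder_share_rises_under_bottleneck(default_panel):
    """A bottlenecked crossing program concentrates ancestry: the top-11
    founder share of late-phase cultivars is high."""
    matrix, truth = default_panel
    g = PedigreeGraph.from_frame(truth.pedigree)
    acc = matrix.accessions
    g2 = [a for a in acc.loc[acc["group"] == "group2", "accession_id"]
          if a in g.edges]
    g3 = [a for a in acc.loc[acc["group"] == "group3", "accession_id"]
          if a in g.edges]
    share2 = top_founder_share(founder_frequencies(g, g2), 11)
    share3 = top_founder_share(founder_frequencies(g, g3), 11)
    assert share2 >= 0.7 and share3 >= 0.7


def test_classify_admixed_threshold_strict():
    q = pd.DataFrame([[0.9, 0.1, 0.0, 0.0],
                      [0.5, 0.3, 0.1, 0.1],
                      [0.8, 0.2, 0.0, 0.0]],
                     index=["a", "b", "c"],
                     columns=list("WXYZ"))
    flags = classify_admixed(q)
    assert flags.tolist() == [False, True, False]


def test_identical_groups_share_letter():
    q = pd.DataFrame({"comp": [0.5, 0.5, 0.5, 0.5, 0.5, 0.5]},
                     index=[f"a{i}" for i in range(6)])
    res = group_component_stats(q, {"A": ["a0", "a1", "a2"],
                                    "B": ["a3", "a4", "a5"]})
    letters = dict(zip(res.stats["group"], res.stats["letters"]))
    assert letters["A"] == letters["B"] == "a"


def test_separated_groups_get_distinct_letters():
    q = pd.DataFrame({"comp": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0]},
                     index=[f"a{i}" for i in range(6)])
    res = group_component_stats(q, {"A": ["a0", "a1", "a2"],
                                    "B": ["a3", "a4", "a5"]})
    row_a = res.stats[res.stats["group"] == "A"].iloc[0]
    row_b = res.stats[res.stats["group"] == "B"].iloc[0]
    assert row_a["mean"] == pytest.approx(1.0)
    assert row_b["mean"] == pytest.approx(0.0)
    assert row_a["se"] == pytest.approx(0.0)
    assert set(row_a["letters"]).isdisjoint(set(row_b["letters"]))


def test_letters_consistent_with_adjusted_p():
    rng = np.random.default_rng(4)
    q = pd.DataFrame({"c1": rng.random(20), "c2": rng.random(20)},
                     index=[f"a{i}" for i in range(20)])
    groups = {"A": [f"a{i}" for i in range(0, 7)],
              "B": [f"a{i}" for i in range(7, 13)],
              "C": [f"a{i}" for i in range(13, 20)]}
    res = group_component_stats(q, groups, alpha=0.05)
    for comp in ("c1", "c2"):
        letters = dict(zip(
            res.stats.loc[res.stats["component"] == comp, "group"],
            res.stats.loc[res.stats["component"] == comp, "letters"]))
        assert all(letters.values())  # no empty letter sets
        pw = res.pairwise[res.pairwise["component"] == comp]
        for _, row in pw.iterrows():
            share = bool(set(letters[row["group_a"]])
                         & set(letters[row["group_b"]]))
            if row["p_adjusted"] >= 0.05:
                assert share  # non-different groups must share a letter


def test_group_stats_cardinality():
    rng = np.random.default_rng(9)
    raw = rng.dirichlet(np.ones(4), size=24)
    q = pd.DataFrame(raw, columns=list("WXYZ"),
                     index=[f"a{i}" for i in range(24)])
    groups = {k: [f"a{i}" for i in range(6 * j, 6 * j + 6)]
              for j, k in enumerate(["g1", "g2", "g3", "ni"])}
    res = group_component_stats(q, groups)
    assert len(res.stats) == 16                      # 4 groups x 4 components
    assert (res.pairwise.groupby("component").size() == 6).all()


def test_simple_matching_examples():
    calls = np.zeros((3, 10), dtype=np.int8)
    calls[1] = 1 - calls[0]               # complementary everywhere
    calls[2, :2] = 1                      # differs at 2 of 10
    m = mk_matrix(calls)
    d = simple_matching_distance(m)
    assert d.iloc[0, 0] == 0.0
    assert d.iloc[0, 1] == pytest.approx(1.0)
    assert d.iloc[0, 2] == pytest.approx(0.2)


def test_simple_matching_symmetric_and_missing_aware():
    rng = np.random.default_rng(6)
    calls = rng.choice([0, 1, MISSING], p=[0.4, 0.4, 0.2],
                       size=(12, 30)).astype(np.int8)
    m = mk_matrix(calls)
    d = simple_matching_distance(m).to_numpy()
    assert np.allclose(d, d.T, equal_nan=True)
    assert np.allclose(np.diag(d), 0.0)


def test_no_comparable_sites_gives_nan():
    calls = np.array([[0, MISSING], [MISSING, 1], [0, 1]], dtype=np.int8)
    m = mk_matrix(calls)
    d = simple_matching_distance(m)
    assert np.isnan(d.iloc[0, 1])
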