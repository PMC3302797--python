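"""Pedigree founder analysis and admixture-group statistics.

Founder frequencies follow the breeding-records convention: every ancestor
occurrence over all pedigree paths is counted, except that subtrees reached
through a recurrent-parent edge (backcross donors' repeated partner) are
skipped. Group-level admixture statistics summarize an externally supplied
Q-matrix per breeding-phase group with Mann-Whitney tests, Bonferroni
correction, and a compact letter display. A simple-matching distance matrix
is computed for external tree building.
"""

from __future__ import annotations

import string
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import MISSING, DataError, GenotypeMatrix


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

@dataclass
class PedigreeGraph:
    """Cultivar -> parents DAG with recurrent-parent flags.

    ``edges[child]`` is a list of (parent, is_recurrent) pairs; founders are
    nodes with no recorded parents.
    """

    edges: dict[str, list[tuple[str, bool]]]

    @classmethod
    def from_frame(cls, ped: pd.DataFrame) -> "PedigreeGraph":
        edges: dict[str, list[tuple[str, bool]]] = {}
        for _, row in ped.iterrows():
            child = row["child"]
            rec = str(row.get("recurrent_parent", "") or "")
            parents = [p for p in (row["parent1"], row["parent2"])
                       if isinstance(p, str) and p]
            if not 1 <= len(parents) <= 2:
                raise DataError(f"cultivar {child!r} has {len(parents)} parents")
            edges[child] = [(p, p == rec) for p in parents]
        graph = cls(edges)
        graph.check_acyclic()
        return graph

    @property
    def nodes(self) -> set[str]:
        out = set(self.edges)
        for plist in self.edges.values():
            out.update(p for p, _ in plist)
        return out

    @property
    def founders(self) -> set[str]:
        return {n for n in self.nodes if n not in self.edges}

    def check_acyclic(self) -> None:
        WHITE, GREY, BLACK = 0, 1, 2
        color: dict[str, int] = {}

        def visit(node: str) -> None:
            color[node] = GREY
            for parent, _ in self.edges.get(node, ()):
                c = color.get(parent, WHITE)
                if c == GREY:
                    raise DataError(f"pedigree cycle through {parent!r}")
                if c == WHITE:
                    visit(parent)
            color[node] = BLACK

        for node in list(self.edges):
            if color.get(node, WHITE) == WHITE:
                visit(node)

    def founder_occurrences(self, cultivar: str,
                            skip_recurrent: bool = True) -> Counter:
        """Occurrences of each founder over all root-ward paths from
        ``cultivar``, skipping recurrent-parent edges."""
        memo: dict[str, Counter] = {}

        def occ(node: str) -> Counter:
            if node in memo:
                return memo[node]
            plist = self.edges.get(node)
            if not plist:
                out = Counter({node: 1})
            else:
                out = Counter()
                for parent, is_rec in plist:
                    if skip_recurrent and is_rec:
                        continue
                    out.update(occ(parent))
            memo[node] = out
            return out

        if cultivar not in self.nodes:
            raise DataError(f"cultivar {cultivar!r} not in pedigree")
        return occ(cultivar)


def founder_frequencies(pedigree: PedigreeGraph,
                        cultivars: Iterable[str],
                        skip_recurrent: bool = True,
                        unique_ancestors: bool = False) -> pd.DataFrame:
    """Founder shares over a cultivar set.

    Default counts path occurrences (a founder reached by two paths counts
    twice); ``unique_ancestors=True`` counts each founder at most once per
    cultivar. Shares sum to 1 over founders whenever any occurrence is
    counted.
    """
    total: Counter = Counter()
    for cultivar in cultivars:
        occ = pedigree.founder_occurrences(cultivar, skip_recurrent)
        if unique_ancestors:
            occ = Counter(dict.fromkeys(occ, 1))
        total.update(occ)
    grand = sum(total.values())
    rows = [{"founder": f, "occurrences": n,
             "share": n / grand if grand else float("nan")}
            for f, n in total.most_common()]
    return pd.DataFrame(rows, columns=["founder", "occurrences", "share"])


def top_founder_share(freqs: pd.DataFrame, k: int = 11) -> float:
    """Summed share of the k most common founders."""
    return float(freqs.nlargest(k, "share")["share"].sum()) if len(freqs) else 0.0


# ---------------------------------------------------------------------------
# admixture Q-matrix statistics
# ---------------------------------------------------------------------------

def classify_admixed(q: pd.DataFrame, threshold: float = 0.8) -> pd.Series:
    """An accession is admixed iff its largest ancestral component is
    strictly below ``threshold`` (i.e. no single ancestor contributes >= 0.8
    of its alleles)."""
    return q.max(axis=1) < threshold


@dataclass
class GroupComponentStats:
    stats: pd.DataFrame        # component, group, mean, se, n, letters
    pairwise: pd.DataFrame     # component, group_a, group_b, p_raw, p_adjusted


def _compact_letters(groups_desc: list[str],
                     differs: Mapping[tuple[str, str], bool]) -> dict[str, str]:
    """Greedy compact letter display over groups sorted by descending mean:
    a group joins every existing letter cluster it does not significantly
    differ from (all members), else opens a new letter."""
    clusters: list[set[str]] = []
    for g in groups_desc:
        joined = False
        for members in clusters:
            if all(not differs[tuple(sorted((g, m)))] for m in members):
                members.add(g)
                joined = True
        if not joined:
            clusters.append({g})
    letters = {g: "" for g in groups_desc}
    for letter, members in zip(string.ascii_lowercase, clusters):
        for g in members:
            letters[g] += letter
    return letters


def group_component_stats(q: pd.DataFrame,
                          groups: Mapping[str, Sequence[str]],
                          alpha: float = 0.05) -> GroupComponentStats:
    """Per (group, component) means +/- SE with pairwise Mann-Whitney tests,
    Bonferroni-adjusted per component, and letter codes.

    ``groups`` maps group label -> accession ids (Q-matrix index). SE is the
    sample standard deviation / sqrt(n); groups of size < 2 get NaN SE.
    """
    if len(groups) < 2:
        raise DataError("need >= 2 groups")
    pair_list = []
    names = list(groups)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pair_list.append((names[i], names[j]))
    n_pairs = len(pair_list)
    stat_rows, pw_rows = [], []
    for comp in q.columns:
        values = {g: q.loc[list(ids), comp].to_numpy(dtype=float)
                  for g, ids in groups.items()}
        differs: dict[tuple[str, str], bool] = {}
        for ga, gb in pair_list:
            va, vb = values[ga], values[gb]
            if np.array_equal(va, vb) or (np.ptp(np.concatenate([va, vb])) == 0):
                p_raw = 1.0
            else:
                p_raw = float(stats.mannwhitneyu(va, vb,
                                                 alternative="two-sided").pvalue)
            p_adj = min(1.0, p_raw * n_pairs)
            differs[tuple(sorted((ga, gb)))] = p_adj < alpha
            pw_rows.append({"component": comp, "group_a": ga, "group_b": gb,
                            "p_raw": p_raw, "p_adjusted": p_adj})
        order = sorted(names, key=lambda g: -np.mean(values[g]))
        letters = _compact_letters(order, differs)
        for g in names:
            v = values[g]
            se = float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan")
            stat_rows.append({"component": comp, "group": g,
                              "mean": float(np.mean(v)), "se": se,
                              "n": len(v), "letters": letters[g]})
    return GroupComponentStats(pd.DataFrame(stat_rows), pd.DataFrame(pw_rows))


# ---------------------------------------------------------------------------
# simple-matching distance
# ---------------------------------------------------------------------------

def simple_matching_distance(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise accession distance 1 - (matching calls / comparable calls)
    over SNPs non-missing in both accessions; NaN where no SNP is comparable.

    The resulting square table (PHYLIP-exportable via io.write_phylip_square)
    is the input for external weighted neighbor-joining tree construction.
    """
    if matrix.n_accessions < 2:
        raise DataError("need >= 2 accessions")
    calls = matrix.calls
    n = matrix.n_accessions
    dist = np.zeros((n, n))
    present = calls != MISSING
    for i in range(n):
        both = present[i] & present
        comparable = both.sum(axis=1)
        matches = ((calls[i] == calls) & both).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist[i] = 1.0 - np.where(comparable > 0, matches / comparable, np.nan)
    np.fill_diagonal(dist, 0.0)
    ids = matrix.accessions["accession_id"].tolist()
    return pd.DataFrame(dist, index=ids, columns=ids)
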