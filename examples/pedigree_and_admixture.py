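"""Pedigree founder concentration and admixture-group statistics.

Counts founder occurrences over all pedigree paths (skipping recurrent
backcross parents), and summarizes the simulation's true admixture Q-matrix
per breeding-phase group with Mann-Whitney letters.
"""

import haplodyn as hd

matrix, truth = hd.simulate_panel(seed=1)
graph = hd.PedigreeGraph.from_frame(truth.pedigree)
acc = matrix.accessions

for group in ("group2", "group3"):
    ids = [a for a in acc.loc[acc["group"] == group, "accession_id"]
           if a in graph.edges]
    freqs = hd.founder_frequencies(graph, ids)
    share = hd.top_founder_share(freqs, 11)
    print(f"{group}: {len(freqs)} founders reached; "
          f"top-11 share = {share:.2f}")

q = truth.q_matrix
admixed = hd.classify_admixed(q, threshold=0.8)
print(f"admixed accessions (max component < 0.8): {int(admixed.sum())} "
      f"of {len(q)}")

grouping = {g: [a for a in acc.loc[(acc['group'] == g)
                                   & (acc['water_regime'] == 'irrigated'),
                                   'accession_id']]
            for g in ("group1", "group2", "group3")}
stats = hd.group_component_stats(q, grouping)
first = q.columns[0]
rows = stats.stats[stats.stats["component"] == first]
print(f"component {first}: " + ", ".join(
    f"{r['group']} {r['mean']:.3f}+-{r['se']:.3f} ({r['letters']})"
    for _, r in rows.iterrows()))
# A top-11 founder share near or above 0.7 in the improved phases mirrors
# the ancestry concentration that a narrow crossing program produces;
# different letters mark groups whose component means differ after
# Bonferroni-corrected Mann-Whitney tests.
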