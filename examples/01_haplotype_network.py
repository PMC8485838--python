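"""Collapse a cpDNA alignment into haplotypes and build the MJ network.

Generates a small study-shaped dataset, filters it to complete columns,
collapses identical sequences into haplotypes and prints the
median-joining network.  Each edge weight is the number of mutation
steps between its endpoint haplotypes; 'mv' nodes are inferred
(unsampled) median vectors.
"""

from cpphylo.alignment import filter_complete_columns
from cpphylo.haplotypes import collapse_haplotypes, median_joining_network
from cpphylo.synthetic import FixtureSpec, generate_study_like

aln, meta = generate_study_like(FixtureSpec(seed=42))
filtered, classes = filter_complete_columns(aln)
print(f"{aln.n_samples} sequences, {filtered.length} complete columns, "
      f"{len(classes.polymorphic)} polymorphic "
      f"({len(classes.parsimony_informative)} parsimony-informative)")

table = collapse_haplotypes(filtered, meta)
print(f"{table.n_haplotypes} haplotypes among {table.n_total} samples")
print(table.population_summary().head(6).to_string(index=False))

net = median_joining_network(table)
print(f"\nnetwork: {net.graph.number_of_nodes()} nodes "
      f"({len(net.median_labels)} median vectors), "
      f"{net.graph.number_of_edges()} edges")
for u, v, w in sorted(net.graph.edges(data="weight"))[:10]:
    print(f"  {u} -- {v}  ({w} step{'s' if w > 1 else ''})")
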