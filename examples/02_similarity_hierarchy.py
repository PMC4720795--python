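"""Build the hierarchical similarity graph for three overlapping sets.

Terminal nodes are the individual sets; each higher-level node is a maximal
biclique — a group of sets together with every gene common to all of them.
Edges are Hasse covers: {A,B,C} -> {A,B} but not {A,B,C} -> {C}, because
{B,C} lies in between.  Note there is no {A,C} node: every gene shared by A
and C is also in B, so {A,C} is not closed.
"""

from genelattice import build_hierarchy, cohesiveness_summary, mark_emphasis
from genelattice.bipartite import BipartiteGraph

graph = BipartiteGraph(
    {"A": frozenset("123"), "B": frozenset("234"), "C": frozenset("345")},
    {"A": "Mm", "B": "Hs", "C": "Rn"},
)
h = build_hierarchy(graph)
print(f"{h.n_nodes} nodes, {h.n_edges} edges")
for sig, node in h.nodes.items():
    print(f"  level {node.level}: {{{','.join(sorted(sig))}}} "
          f"genes={{{','.join(sorted(node.genes))}}}")
for parent, child in h.edges:
    print(f"  {{{','.join(sorted(parent))}}} -> {{{','.join(sorted(child))}}}")

h = mark_emphasis(h, {"2"})  # pretend gene "2" is a known gene
flagged = [sorted(s) for s, n in h.nodes.items() if n.emphasis_hit]
print("nodes containing the known gene:", flagged)
print(cohesiveness_summary(h, n_sets=3, min_genes=2))
# 3 of the 4 possible multi-set combinations are populated; none holds more
# than 2 genes, so the corpus is cohesive but its intersections are thin.
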