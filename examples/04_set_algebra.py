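"""Boolean algebra over gene sets: union, intersection, occurrence threshold.

The threshold mode generalizes both: genes in >= 1 set is the union, genes
in all n sets is the intersection, and intermediate k picks up genes with
recurrent but not universal support — the usual way a curated "known genes"
emphasis list is distilled from many overlapping annotation sets.
"""

from genelattice import AlgebraSpec, GeneSet, combine

a = GeneSet(set_id="A", members=frozenset({"1", "2"}))
b = GeneSet(set_id="B", members=frozenset({"2", "3"}))
c = GeneSet(set_id="C", members=frozenset({"3", "4"}))

for mode, k in (("union", None), ("intersect", None), ("threshold", 2)):
    result = combine(AlgebraSpec(mode, (a, b, c), threshold=k))
    print(f"{result.set_id}: {sorted(result.members)}")
# union -> {1,2,3,4}; intersection -> {} (no gene is in all three);
# threshold k=2 -> {2,3}, the genes supported by at least two sets.

k1 = combine(AlgebraSpec("threshold", (a, b, c), threshold=1))
k3 = combine(AlgebraSpec("threshold", (a, b, c), threshold=3))
print("k=1 equals union:", k1.members == combine(AlgebraSpec("union", (a, b, c))).members)
print("k=3 equals intersection:",
      k3.members == combine(AlgebraSpec("intersect", (a, b, c))).members)
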