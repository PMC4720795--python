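"""The hierarchical similarity graph: a Hasse diagram over populated
gene-set combinations.

Nodes are the closed set-groups with non-empty gene intersection (exactly
the maximal bicliques of the incidence graph) plus a forced terminal node
for every individual gene set, even when that singleton group is not closed
(e.g. a set wholly contained in another).  Levels count the sets in a
node's signature: terminals sit at level 1; higher levels hold larger
combinations with smaller intersections.  Edges are the cover relation of
strict signature containment — the containment order with transitive edges
removed — directed from the larger combination (parent) to the smaller
(child).  Along every edge the gene payload grows anti-monotonically:
genes(parent) is a subset of genes(child).

Empty sets (possible after bootstrap resampling) keep their terminal node
with an empty payload but can never enter a combination node, since
combination nodes require a non-empty intersection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

from .bipartite import BipartiteGraph

__all__ = [
    "HierarchyNode",
    "HierarchyGraph",
    "build_hierarchy",
    "mark_emphasis",
    "emphasis_depth_profile",
    "cohesiveness_summary",
]

Signature = frozenset[str]


@dataclass(frozen=True)
class HierarchyNode:
    """One populated gene-set combination (or forced terminal)."""

    signature: Signature
    genes: frozenset[str]
    emphasis_hit: bool = False
    emphasis_genes_present: frozenset[str] = frozenset()

    @property
    def level(self) -> int:
        return len(self.signature)

    @property
    def is_terminal(self) -> bool:
        return self.level == 1

    def sort_key(self) -> tuple[int, tuple[str, ...]]:
        return (-self.level, tuple(sorted(self.signature)))


@dataclass
class HierarchyGraph:
    """Nodes keyed by signature, Hasse cover edges, and a per-level index."""

    nodes: dict[Signature, HierarchyNode]
    edges: list[tuple[Signature, Signature]]  # (parent, child), parent strictly contains child
    level_index: dict[int, list[Signature]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.level_index:
            idx: dict[int, list[Signature]] = {}
            for sig in self.nodes:
                idx.setdefault(len(sig), []).append(sig)
            self.level_index = {
                lvl: sorted(sigs, key=lambda s: tuple(sorted(s)))
                for lvl, sigs in sorted(idx.items())
            }

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def max_level(self) -> int:
        return max(self.level_index, default=0)

    def children(self, sig: Signature) -> list[Signature]:
        return [c for p, c in self.edges if p == sig]

    def parents(self, sig: Signature) -> list[Signature]:
        return [p for p, c in self.edges if c == sig]

    def combination_nodes(self) -> list[HierarchyNode]:
        """Nodes at level >= 2, i.e. genuine multi-set intersections."""
        return [n for n in self.nodes.values() if n.level >= 2]


def _edge_key(edge: tuple[Signature, Signature]) -> tuple:
    p, c = edge
    return (-len(p), tuple(sorted(p)), -len(c), tuple(sorted(c)))


def _hasse_edges(signatures: Iterable[Signature]) -> list[tuple[Signature, Signature]]:
    """Cover relation of strict containment over *signatures* via bitmasks."""
    sigs = list(signatures)
    universe = sorted({s for sig in sigs for s in sig})
    bit = {s: 1 << i for i, s in enumerate(universe)}
    mask_of = {sig: sum(bit[s] for s in sig) for sig in sigs}
    # scan candidates largest-first; a subset is a cover child unless it is
    # contained in an already accepted (larger or equal level) child
    order = sorted(sigs, key=lambda s: (-len(s), tuple(sorted(s))))
    edges: list[tuple[Signature, Signature]] = []
    for parent in order:
        pm = mask_of[parent]
        accepted: list[int] = []
        for child in order:
            cm = mask_of[child]
            if cm == pm or cm & pm != cm:
                continue
            if any(cm & am == cm for am in accepted):
                continue
            accepted.append(cm)
            edges.append((parent, child))
    edges.sort(key=_edge_key)
    return edges


def build_hierarchy(graph: BipartiteGraph) -> HierarchyGraph:
    """Assemble the hierarchy from an incidence graph.

    Node set = closed set-groups with non-empty intersection, plus every
    singleton set-group as a forced terminal.  Payload of a node is the
    intersection of its member sets.
    """
    from .bicliques import enumerate_maximal_bicliques

    nodes: dict[Signature, HierarchyNode] = {}
    for bc in enumerate_maximal_bicliques(graph):
        nodes[bc.set_group] = HierarchyNode(signature=bc.set_group, genes=bc.gene_group)
    for set_id in graph.set_vertices:
        sig = frozenset([set_id])
        if sig not in nodes:
            nodes[sig] = HierarchyNode(signature=sig, genes=graph.genes_of(set_id))
    ordered = dict(
        sorted(nodes.items(), key=lambda kv: kv[1].sort_key())
    )
    return HierarchyGraph(nodes=ordered, edges=_hasse_edges(ordered))


def mark_emphasis(h: HierarchyGraph, emphasis: Iterable[str]) -> HierarchyGraph:
    """Flag every node whose payload meets the emphasis (known-gene) list.

    Returns a new graph; ``emphasis_genes_present`` records the overlap.
    """
    emphasis_set = frozenset(emphasis)
    nodes = {
        sig: replace(
            node,
            emphasis_hit=bool(node.genes & emphasis_set),
            emphasis_genes_present=node.genes & emphasis_set,
        )
        for sig, node in h.nodes.items()
    }
    return HierarchyGraph(nodes=nodes, edges=list(h.edges),
                          level_index=dict(h.level_index))


def emphasis_depth_profile(h: HierarchyGraph) -> dict:
    """Per-level node/flagged-node counts after :func:`mark_emphasis`.

    The interesting summary is how far up the hierarchy previously annotated
    genes reach: a low ``max_flagged_level`` relative to ``max_level`` means
    the most intersected genes are *not* on the known list.
    """
    per_level: dict[int, tuple[int, int]] = {}
    for lvl, sigs in h.level_index.items():
        flagged = sum(1 for s in sigs if h.nodes[s].emphasis_hit)
        per_level[lvl] = (len(sigs), flagged)
    flagged_levels = [lvl for lvl, (_, f) in per_level.items() if f > 0]
    return {
        "per_level": per_level,
        "max_level": h.max_level,
        "max_flagged_level": max(flagged_levels, default=0),
    }


def cohesiveness_summary(h: HierarchyGraph, n_sets: int, min_genes: int) -> dict:
    """How cohesive is the corpus?  Reports populated higher-order
    combinations against the possible ones.

    ``possible`` counts the combinations of two or more sets, ``2**n - n - 1``;
    ``populated`` counts hierarchy nodes at level >= 2; ``populated_gt_min``
    counts those whose payload exceeds *min_genes* genes.  Few large
    combinations indicate cohesive experimental results; many small ones,
    fragmentation.
    """
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    possible = (1 << n_sets) - n_sets - 1 if n_sets >= 1 else 0
    combos = h.combination_nodes()
    populated = len(combos)
    populated_gt = sum(1 for n in combos if len(n.genes) > min_genes)
    return {
        "n_sets": n_sets,
        "min_genes": min_genes,
        "possible": possible,
        "populated": populated,
        "populated_gt_min": populated_gt,
        "populated_ratio": populated / possible if possible else 0.0,
        "populated_gt_min_ratio": populated_gt / possible if possible else 0.0,
    }
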