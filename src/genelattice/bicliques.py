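"""Maximal biclique enumeration on the gene x set incidence graph.

A biclique is a pair (gene_group, set_group) in which every gene belongs to
every set; it is maximal when neither side can be extended.  Maximal
bicliques with a non-empty gene side correspond one-to-one with *closed*
set-groups T — those equal to the full collection of sets containing their
common gene intersection (formal concepts of the incidence relation).

The enumerator exploits a classical fact of concept lattices: every closed
set-group with a non-empty gene side is an intersection of per-gene
"intents" (the collection of sets a gene belongs to), and conversely every
non-empty such intersection is closed.  Closing the distinct gene intents
under pairwise intersection therefore yields exactly the maximal bicliques.
Set-groups are packed into integer bitmasks, so intersection and subset
tests are single machine-word operations for corpora of up to a few dozen
sets and stay cheap far beyond that.
"""

from __future__ import annotations

from dataclasses import dataclass

from .bipartite import BipartiteGraph
from .errors import GeneLatticeError

__all__ = [
    "Biclique",
    "enumerate_maximal_bicliques",
    "brute_force_bicliques",
    "is_maximal",
]

BRUTE_FORCE_MAX_SETS = 20


@dataclass(frozen=True)
class Biclique:
    """A maximal complete bipartite subgraph of the incidence graph."""

    gene_group: frozenset[str]
    set_group: frozenset[str]

    def sort_key(self) -> tuple[int, tuple[str, ...]]:
        # |set_group| descending, then lexicographic set_group
        return (-len(self.set_group), tuple(sorted(self.set_group)))


class _SetIndex:
    """Bidirectional set_id <-> bit position mapping for one graph."""

    def __init__(self, graph: BipartiteGraph):
        self.ids: tuple[str, ...] = graph.set_vertices
        self.bit_of = {s: 1 << i for i, s in enumerate(self.ids)}

    def to_mask(self, sets: frozenset[str]) -> int:
        mask = 0
        for s in sets:
            mask |= self.bit_of[s]
        return mask

    def to_sets(self, mask: int) -> frozenset[str]:
        return frozenset(
            self.ids[i] for i in range(len(self.ids)) if mask >> i & 1
        )


def _gene_intents(graph: BipartiteGraph, index: _SetIndex) -> dict[str, int]:
    return {g: index.to_mask(graph.sets_of(g)) for g in graph.gene_vertices}


def _closed_masks(intents: dict[str, int]) -> set[int]:
    """All non-empty intersections of the distinct gene intents."""
    base = set(intents.values())
    closed = set(base)
    frontier = list(base)
    while frontier:
        t = frontier.pop()
        for b in base:
            u = t & b
            if u and u not in closed:
                closed.add(u)
                frontier.append(u)
    return closed


def _extent(intents: dict[str, int], mask: int) -> frozenset[str]:
    return frozenset(g for g, m in intents.items() if m & mask == mask)


def enumerate_maximal_bicliques(graph: BipartiteGraph) -> list[Biclique]:
    """Enumerate every maximal biclique with non-empty sides, each once,
    ordered by set-group size descending then lexicographic set-group."""
    index = _SetIndex(graph)
    intents = _gene_intents(graph, index)
    out = [
        Biclique(gene_group=_extent(intents, mask), set_group=index.to_sets(mask))
        for mask in _closed_masks(intents)
    ]
    out.sort(key=Biclique.sort_key)
    return out


def brute_force_bicliques(graph: BipartiteGraph) -> list[Biclique]:
    """Exhaustive oracle: walk all non-empty set-groups, keep the closed ones
    with a non-empty intersection.  Only for small instances."""
    n = len(graph.set_vertices)
    if n > BRUTE_FORCE_MAX_SETS:
        raise GeneLatticeError(
            f"brute force limited to {BRUTE_FORCE_MAX_SETS} sets (got {n}); "
            "use enumerate_maximal_bicliques"
        )
    index = _SetIndex(graph)
    genes_of = {s: graph.genes_of(s) for s in graph.set_vertices}
    seen: set[int] = set()
    out: list[Biclique] = []
    for mask in range(1, 1 << n):
        group = index.to_sets(mask)
        inter = frozenset.intersection(*(genes_of[s] for s in group))
        if not inter:
            continue
        closure = frozenset(
            s for s in graph.set_vertices if inter <= genes_of[s]
        )
        if closure != group:
            continue
        if mask not in seen:
            seen.add(mask)
            out.append(Biclique(gene_group=inter, set_group=group))
    out.sort(key=Biclique.sort_key)
    return out


def is_maximal(graph: BipartiteGraph, candidate: Biclique) -> bool:
    """True iff *candidate* is complete and neither side is extendable."""
    if not candidate.gene_group or not candidate.set_group:
        return False
    for s in candidate.set_group:
        if not candidate.gene_group <= graph.genes_of(s):
            return False  # not complete
    for g in graph.gene_vertices:
        if g not in candidate.gene_group and candidate.set_group <= graph.sets_of(g):
            return False  # gene side extendable
    for s in graph.set_vertices:
        if s not in candidate.set_group and candidate.gene_group <= graph.genes_of(s):
            return False  # set side extendable
    return True
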