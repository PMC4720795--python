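"""Bipartite incidence between harmonized gene clusters and gene sets.

One partite set holds gene (homology-cluster) vertices, the other holds
gene-set vertices; an edge records membership.  Vertex orderings are
lexicographic so every downstream enumeration and export is reproducible.
"""

from __future__ import annotations

from typing import Mapping

from .errors import GeneLatticeError
from .genesets import HarmonizedCollection

__all__ = ["BipartiteGraph", "build_incidence"]


class BipartiteGraph:
    """Immutable gene x set incidence structure with degree queries."""

    def __init__(
        self,
        genes_of_set: Mapping[str, frozenset[str]],
        species_of_set: Mapping[str, str],
        empty_flagged: frozenset[str] = frozenset(),
    ):
        self._genes_of_set = {s: frozenset(g) for s, g in genes_of_set.items()}
        self.species_of_set = dict(species_of_set)
        self.empty_flagged = frozenset(empty_flagged)
        for set_id, genes in self._genes_of_set.items():
            if not genes and set_id not in self.empty_flagged:
                raise GeneLatticeError(
                    f"set {set_id!r} has no members and is not flagged empty"
                )
        sets_of_gene: dict[str, set[str]] = {}
        for set_id, genes in self._genes_of_set.items():
            for g in genes:
                sets_of_gene.setdefault(g, set()).add(set_id)
        self._sets_of_gene = {g: frozenset(s) for g, s in sets_of_gene.items()}
        self.gene_vertices: tuple[str, ...] = tuple(sorted(self._sets_of_gene))
        self.set_vertices: tuple[str, ...] = tuple(sorted(self._genes_of_set))
        self.n_edges = sum(len(g) for g in self._genes_of_set.values())

    def genes_of(self, set_id: str) -> frozenset[str]:
        try:
            return self._genes_of_set[set_id]
        except KeyError:
            raise GeneLatticeError(f"unknown set {set_id!r}") from None

    def sets_of(self, gene: str) -> frozenset[str]:
        try:
            return self._sets_of_gene[gene]
        except KeyError:
            raise GeneLatticeError(f"unknown gene {gene!r}") from None

    def gene_degree(self, gene: str) -> int:
        """Number of gene sets containing *gene* — the prioritization statistic."""
        return len(self.sets_of(gene))

    def species_coverage(self, gene: str) -> int:
        """Number of distinct species among the sets containing *gene*."""
        return len({self.species_of_set[s] for s in self.sets_of(gene)})

    def sorted_edges(self) -> list[tuple[str, str]]:
        return sorted(
            (g, s) for s, genes in self._genes_of_set.items() for g in genes
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BipartiteGraph):
            return NotImplemented
        return (
            self._genes_of_set == other._genes_of_set
            and self.species_of_set == other.species_of_set
        )

    def __repr__(self) -> str:
        return (
            f"BipartiteGraph(genes={len(self.gene_vertices)}, "
            f"sets={len(self.set_vertices)}, edges={self.n_edges})"
        )


def build_incidence(collection: HarmonizedCollection) -> BipartiteGraph:
    """Build the incidence graph of a harmonized collection (one edge per
    gene-set membership)."""
    return BipartiteGraph(
        genes_of_set={gs.set_id: gs.members for gs in collection.sets},
        species_of_set={gs.set_id: gs.species for gs in collection.sets},
        empty_flagged=collection.empty_flagged
        | frozenset(gs.set_id for gs in collection.sets if not gs.members),
    )
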