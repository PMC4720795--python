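"""Degree-based gene prioritization.

Genes recurring across many independent experimental gene sets are strong
candidates even when no single study highlighted them.  Ranking is by
set-membership degree (descending), ties broken by species coverage
(descending — cross-species recurrence is stronger evidence) and then
lexicographic id.  Genes already on the curated "known" list are flagged so
that highly connected *novel* genes stand out.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable

from .bipartite import BipartiteGraph
from .genesets import GeneSet

__all__ = ["PriorityRecord", "rank_genes", "novel_gene_report", "report_to_tsv"]

TSV_COLUMNS = ("gene", "degree", "fraction_of_sets", "n_species", "known", "rank")


@dataclass(frozen=True)
class PriorityRecord:
    gene: str
    degree: int
    fraction_of_sets: float
    n_species: int
    known: bool
    rank: int


def rank_genes(graph: BipartiteGraph, known: GeneSet | Iterable[str]) -> list[PriorityRecord]:
    """Rank every gene vertex of *graph*; ``known`` holds cluster ids."""
    known_ids = frozenset(known.members if isinstance(known, GeneSet) else known)
    n_sets = len(graph.set_vertices)
    keyed = sorted(
        graph.gene_vertices,
        key=lambda g: (-graph.gene_degree(g), -graph.species_coverage(g), g),
    )
    return [
        PriorityRecord(
            gene=g,
            degree=graph.gene_degree(g),
            fraction_of_sets=graph.gene_degree(g) / n_sets,
            n_species=graph.species_coverage(g),
            known=g in known_ids,
            rank=i,
        )
        for i, g in enumerate(keyed, start=1)
    ]


def novel_gene_report(records: Iterable[PriorityRecord], top_k: int) -> dict:
    """The top_k highest-ranked genes absent from the known list, with the
    single best novel candidate singled out."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    novel = [r for r in records if not r.known]
    top = novel[:top_k]
    return {
        "top_k": top_k,
        "n_novel": len(novel),
        "no_novel_genes": not novel,
        "top_novel_gene": top[0].gene if top else None,
        "records": [asdict(r) for r in top],
    }


def report_to_tsv(records: Iterable[PriorityRecord], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.gene}\t{r.degree}\t{r.fraction_of_sets:.6g}\t"
                f"{r.n_species}\t{str(r.known).lower()}\t{r.rank}\n"
            )
    return path


def report_to_json(records: Iterable[PriorityRecord], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps([asdict(r) for r in records], indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return path
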