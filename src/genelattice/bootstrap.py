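"""Bootstrap consensus pruning of the similarity hierarchy.

Each iteration resamples every gene set's members independently (by default
ceil(0.75 * |set|) draws with replacement, then deduplication), rebuilds the
hierarchy, and records which node signatures and parent->child signature
pairs appear.  Nodes and edges recurring in more than the retention fraction
of iterations (default > 0.50) form the consensus graph.  The matching key
across iterations is the set-group signature: gene payloads fluctuate under
resampling, but which combination of sets a node represents does not.

Randomness comes from one root seed; each iteration consumes its own
deterministically spawned substream, so results are reproducible and the
first k iterations do not change when the iteration count grows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bipartite import build_incidence
from .genesets import GeneSet, GeneSetCollection, HarmonizedCollection
from .hierarchy import HierarchyGraph, build_hierarchy, _edge_key

__all__ = ["BootstrapParams", "ConsensusGraph", "resample_collection", "bootstrap_consensus"]

Signature = frozenset[str]


@dataclass(frozen=True)
class BootstrapParams:
    """Resampling procedure parameters.

    fraction:
        Proportion of each set's members drawn per iteration (0 < f <= 1).
    iterations:
        Number of bootstrap replicates.
    retention:
        Frequency a node/edge must exceed (strictly) to be retained.
    with_replacement:
        Draw with replacement (deduplicated afterwards) or without.
    seed:
        Root seed; mandatory so runs are reproducible.
    """

    seed: int
    fraction: float = 0.75
    iterations: int = 1000
    retention: float = 0.50
    with_replacement: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0 <= self.retention < 1:
            raise ValueError("retention must be in [0, 1)")


@dataclass
class ConsensusGraph:
    """Bootstrap node/edge frequencies plus the retained subgraph."""

    node_freq: dict[Signature, float]
    edge_freq: dict[tuple[Signature, Signature], float]
    retained: HierarchyGraph
    params: BootstrapParams

    def summary(self) -> dict[str, float | int]:
        return {
            "iterations": self.params.iterations,
            "fraction": self.params.fraction,
            "retention": self.params.retention,
            "observed_nodes": len(self.node_freq),
            "observed_edges": len(self.edge_freq),
            "retained_nodes": self.retained.n_nodes,
            "retained_edges": self.retained.n_edges,
        }


def resample_collection(
    collection: HarmonizedCollection,
    fraction: float,
    with_replacement: bool,
    rng: np.random.Generator,
) -> HarmonizedCollection:
    """Resample ceil(fraction * |set|) members of each set independently.

    With replacement, the resample is deduplicated to a set afterwards, so
    sizes can shrink.  Identity case: fraction=1 without replacement returns
    the collection unchanged.  Sets that come out empty are flagged.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    resampled = GeneSetCollection()
    empty: set[str] = set()
    for gs in collection.sets:
        members = gs.sorted_members()  # stable order -> reproducible draws
        k = math.ceil(fraction * len(members))
        if k == 0 or not members:
            chosen: frozenset[str] = frozenset()
        elif with_replacement:
            idx = rng.integers(0, len(members), size=k)
            chosen = frozenset(members[i] for i in idx)
        else:
            idx = rng.choice(len(members), size=k, replace=False)
            chosen = frozenset(members[i] for i in idx)
        if not chosen:
            empty.add(gs.set_id)
        resampled.add(GeneSet(set_id=gs.set_id, label=gs.label, species=gs.species,
                              tier=gs.tier, members=chosen))
    return collection.with_sets(resampled, empty_flagged=frozenset(empty))


def bootstrap_consensus(
    collection: HarmonizedCollection, params: BootstrapParams
) -> ConsensusGraph:
    """Run the resample/rebuild loop and threshold the observed frequencies.

    Retained nodes have frequency strictly above ``params.retention``;
    retained edges additionally require both endpoints retained.  The
    retained graph keeps the payloads of the full-data hierarchy where a
    signature exists there; a signature seen only under resampling carries
    the intersection computed on the full collection.
    """
    root = np.random.SeedSequence(params.seed)
    streams = root.spawn(params.iterations)
    node_counts: dict[Signature, int] = {}
    edge_counts: dict[tuple[Signature, Signature], int] = {}
    for ss in streams:
        rng = np.random.default_rng(ss)
        sample = resample_collection(
            collection, params.fraction, params.with_replacement, rng
        )
        h = build_hierarchy(build_incidence(sample))
        for sig in h.nodes:
            node_counts[sig] = node_counts.get(sig, 0) + 1
        for edge in h.edges:
            edge_counts[edge] = edge_counts.get(edge, 0) + 1

    iters = params.iterations
    node_freq = {sig: c / iters for sig, c in node_counts.items()}
    edge_freq = {e: c / iters for e, c in edge_counts.items()}

    full = build_hierarchy(build_incidence(collection))
    kept_sigs = {sig for sig, f in node_freq.items() if f > params.retention}
    kept_nodes = {}
    for sig in kept_sigs:
        node = full.nodes.get(sig)
        if node is None:
            # combination only closed under resampling; payload on full data
            genes = frozenset.intersection(
                *(collection.sets[s].members for s in sig)
            )
            from .hierarchy import HierarchyNode

            node = HierarchyNode(signature=sig, genes=genes)
        kept_nodes[sig] = node
    kept_edges = sorted(
        (
            e
            for e, f in edge_freq.items()
            if f > params.retention and e[0] in kept_sigs and e[1] in kept_sigs
        ),
        key=_edge_key,
    )
    ordered = dict(sorted(kept_nodes.items(), key=lambda kv: kv[1].sort_key()))
    retained = HierarchyGraph(nodes=ordered, edges=kept_edges)
    return ConsensusGraph(
        node_freq=node_freq, edge_freq=edge_freq, retained=retained, params=params
    )
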