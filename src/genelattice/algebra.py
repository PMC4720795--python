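"""Boolean algebra over gene sets: union, intersection and occurrence
thresholds, plus derivation of a merged "known genes" emphasis list.

The threshold mode keeps genes found in at least k of the input sets, so
k=1 reproduces the union and k=n the intersection.  Inputs are expected to
share an identifier space (harmonize first when mixing species).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .errors import GeneLatticeError
from .genesets import (
    GeneSet,
    GeneSetCollection,
    HarmonizedCollection,
    HomologyMap,
    harmonize,
)

__all__ = ["AlgebraSpec", "combine", "derive_known_genes"]

MODES = ("union", "intersect", "threshold")


@dataclass(frozen=True)
class AlgebraSpec:
    """A combination request: mode, inputs, and (for threshold mode) k."""

    mode: str
    inputs: tuple[GeneSet, ...]
    threshold: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise GeneLatticeError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if not self.inputs:
            raise GeneLatticeError("at least one input set required")
        if self.mode == "threshold":
            if self.threshold is None:
                raise GeneLatticeError("threshold mode requires a threshold k")
            if not 1 <= self.threshold <= len(self.inputs):
                raise GeneLatticeError(
                    f"threshold k={self.threshold} out of range 1..{len(self.inputs)}"
                )


def combine(spec: AlgebraSpec) -> GeneSet:
    """Combine the input sets; the result's label records the provenance."""
    members: frozenset[str]
    if spec.mode == "union":
        members = frozenset().union(*(gs.members for gs in spec.inputs))
    elif spec.mode == "intersect":
        members = frozenset.intersection(*(gs.members for gs in spec.inputs))
    else:
        counts = Counter(g for gs in spec.inputs for g in gs.members)
        members = frozenset(g for g, c in counts.items() if c >= spec.threshold)
    input_ids = ",".join(sorted(gs.set_id for gs in spec.inputs))
    suffix = f";k={spec.threshold}" if spec.mode == "threshold" else ""
    return GeneSet(
        set_id=f"{spec.mode}({input_ids}){suffix}",
        label=f"mode={spec.mode}{suffix};inputs={input_ids}",
        species="mixed" if len({gs.species for gs in spec.inputs}) > 1
        else spec.inputs[0].species,
        tier="V",
        members=members,
    )


def derive_known_genes(
    known_sets: GeneSetCollection, hmap: HomologyMap
) -> GeneSet:
    """Harmonize a collection of curated "known gene" sets and merge them
    into a single emphasis set of cluster ids."""
    if len(known_sets) == 0:
        raise GeneLatticeError("cannot derive known genes from an empty collection")
    hc: HarmonizedCollection = harmonize(known_sets, hmap)
    merged = combine(AlgebraSpec(mode="union", inputs=tuple(hc.sets)))
    return GeneSet(
        set_id="known_genes",
        label=f"union of {len(known_sets)} curated sets",
        species="mixed",
        tier="I",
        members=merged.members,
    )
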