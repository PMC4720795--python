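"""Gene sets, homology maps and cross-species harmonization.

A :class:`GeneSet` is a named collection of gene identifiers produced by one
experiment or curation source, tagged with the species it was measured in and
a provenance tier.  Because different species use different identifier
namespaces, integrative analysis first *harmonizes* every member to the id of
its homology cluster — a group of genes across species treated as a single
entity for intersection purposes.  After harmonization a mouse gene and its
human ortholog are literally the same element, so set intersections are
meaningful across species.

File dialects
-------------
* GMT: ``name<TAB>description<TAB>member1<TAB>member2...`` (UTF-8, lines
  starting with ``#`` are skipped).  Species and tier ride in the description
  field as ``key=value`` tokens separated by ``;`` (e.g. ``species=Mm;tier=III``);
  unknown keys are ignored.
* Homology table: TSV with header ``cluster_id<TAB>species<TAB>gene_id``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .errors import GmtParseError, HomologyMapError

logger = logging.getLogger(__name__)

TIERS = ("I", "II", "III", "IV", "V")

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "HomologyMap",
    "HarmonizedCollection",
    "read_gmt",
    "write_gmt",
    "read_homology_map",
    "write_homology_map",
    "harmonize",
    "identity_map",
]


@dataclass(frozen=True)
class GeneSet:
    """A named, species-tagged collection of gene identifiers.

    Parameters
    ----------
    set_id:
        Opaque unique identifier within a collection.
    label:
        Free-text description.
    species:
        Species code (e.g. ``Mm``, ``Hs``); ``"unknown"`` when unstated.
    tier:
        Provenance grade ``I``–``V`` (public resource .. private submission);
        carried as metadata only, never used for filtering.
    members:
        Gene identifiers, duplicate-free.  May be empty only for sets
        explicitly flagged empty (an edge case of bootstrap resampling).
    universe:
        Optional platform coverage list (the identifiers the assay could have
        reported); metadata for coverage-aware downstream work.
    """

    set_id: str
    label: str = ""
    species: str = "unknown"
    tier: str = "IV"
    members: frozenset[str] = frozenset()
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}; expected one of {TIERS}")
        if self.universe is not None and not self.members <= self.universe:
            missing = sorted(self.members - self.universe)[:5]
            raise ValueError(
                f"set {self.set_id!r}: members outside declared universe, e.g. {missing}"
            )

    @property
    def size(self) -> int:
        return len(self.members)

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


class GeneSetCollection:
    """An ordered, id-unique collection of :class:`GeneSet`."""

    def __init__(self, sets: Iterable[GeneSet] = ()):
        self._sets: dict[str, GeneSet] = {}
        for gs in sets:
            self.add(gs)

    def add(self, gs: GeneSet) -> None:
        if gs.set_id in self._sets:
            raise GmtParseError(f"duplicate set id {gs.set_id!r}")
        self._sets[gs.set_id] = gs

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __len__(self) -> int:
        return len(self._sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        return self._sets[set_id]

    def __contains__(self, set_id: str) -> bool:
        return set_id in self._sets

    @property
    def set_ids(self) -> list[str]:
        return list(self._sets)

    def species(self) -> set[str]:
        return {gs.species for gs in self}

    def n_edges(self) -> int:
        """Total gene→set membership count (sum of set sizes)."""
        return sum(gs.size for gs in self)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self._sets == other._sets

    def __repr__(self) -> str:
        return f"GeneSetCollection(n_sets={len(self)}, n_edges={self.n_edges()})"


def _parse_description(desc: str) -> tuple[str, str, str]:
    """Split a GMT description field into (label, species, tier)."""
    species, tier = "unknown", "IV"
    label_parts: list[str] = []
    for token in desc.split(";"):
        token = token.strip()
        if "=" in token:
            key, _, value = token.partition("=")
            key = key.strip().lower()
            value = value.strip()
            if key == "species":
                species = value
            elif key == "tier":
                tier = value
            # unknown key=value tokens are ignored by contract
        elif token:
            label_parts.append(token)
    return "; ".join(label_parts), species, tier


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file into a :class:`GeneSetCollection`.

    Duplicate members within a line are collapsed with a logged warning;
    a line with fewer than three tab-separated fields is a parse error
    naming the line number; duplicate set ids are an error.
    """
    path = Path(path)
    collection = GeneSetCollection()
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path.name}:{lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
                )
            set_id, desc = fields[0].strip(), fields[1]
            raw_members = [m.strip() for m in fields[2:] if m.strip()]
            members = frozenset(raw_members)
            if len(members) < len(raw_members):
                logger.warning(
                    "%s:%d: set %r: collapsed %d duplicate member(s)",
                    path.name, lineno, set_id, len(raw_members) - len(members),
                )
            label, species, tier = _parse_description(desc)
            collection.add(
                GeneSet(set_id=set_id, label=label, species=species, tier=tier,
                        members=members)
            )
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> Path:
    """Write a collection in the GMT dialect read by :func:`read_gmt`.

    Members are emitted sorted so output is byte-stable for equal inputs.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for gs in collection:
            desc = f"species={gs.species};tier={gs.tier}"
            if gs.label:
                desc += f";{gs.label}"
            fh.write("\t".join([gs.set_id, desc, *gs.sorted_members()]) + "\n")
    return path


class HomologyMap:
    """Many-to-one map from ``(species, gene_id)`` to a homology cluster id."""

    def __init__(self, entries: Iterable[tuple[str, str, str]] = ()):
        # entries are (cluster_id, species, gene_id) triples
        self._map: dict[tuple[str, str], str] = {}
        self._clusters: dict[str, list[tuple[str, str]]] = {}
        for cluster_id, species, gene_id in entries:
            self.add(cluster_id, species, gene_id)

    def add(self, cluster_id: str, species: str, gene_id: str) -> None:
        cluster_id, species, gene_id = cluster_id.strip(), species.strip(), gene_id.strip()
        if not cluster_id:
            raise HomologyMapError("empty cluster_id")
        key = (species, gene_id)
        existing = self._map.get(key)
        if existing is not None:
            if existing != cluster_id:
                raise HomologyMapError(
                    f"conflicting clusters for ({species}, {gene_id}): "
                    f"{existing!r} vs {cluster_id!r}"
                )
            return
        self._map[key] = cluster_id
        self._clusters.setdefault(cluster_id, []).append(key)

    def get(self, species: str, gene_id: str) -> str | None:
        return self._map.get((species, gene_id))

    def members_of(self, cluster_id: str) -> list[tuple[str, str]]:
        return sorted(self._clusters.get(cluster_id, []))

    @property
    def cluster_ids(self) -> list[str]:
        return sorted(self._clusters)

    def __len__(self) -> int:
        return len(self._map)

    def __iter__(self) -> Iterator[tuple[str, str, str]]:
        for (species, gene_id), cluster in sorted(self._map.items(), key=lambda kv: (kv[1], kv[0])):
            yield cluster, species, gene_id

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HomologyMap):
            return NotImplemented
        return self._map == other._map


def read_homology_map(path: str | Path) -> HomologyMap:
    """Read a ``cluster_id / species / gene_id`` TSV into a :class:`HomologyMap`."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    expected = ["cluster_id", "species", "gene_id"]
    if list(frame.columns[:3]) != expected:
        raise HomologyMapError(
            f"{Path(path).name}: expected header {expected}, got {list(frame.columns)}"
        )
    hmap = HomologyMap()
    for cluster_id, species, gene_id in frame[expected].itertuples(index=False):
        hmap.add(cluster_id, species, gene_id)
    return hmap


def write_homology_map(hmap: HomologyMap, path: str | Path) -> Path:
    path = Path(path)
    rows = list(hmap)
    frame = pd.DataFrame(rows, columns=["cluster_id", "species", "gene_id"])
    frame.to_csv(path, sep="\t", index=False)
    return path


def identity_map(collection: GeneSetCollection) -> HomologyMap:
    """Map every (species, member) of *collection* to itself — useful to show
    harmonization is idempotent on an already harmonized collection."""
    hmap = HomologyMap()
    for gs in collection:
        for member in gs.members:
            hmap.add(member, gs.species, member)
    return hmap


@dataclass
class HarmonizedCollection:
    """Gene sets whose members live in the shared homology-cluster space.

    ``provenance`` maps each cluster id used by the collection back to the
    contributing ``(species, gene_id)`` pairs; ``unmapped_count`` counts the
    distinct raw pairs that had no homology entry and were therefore kept as
    deterministic singleton clusters (``solo:<species>:<gene_id>``).
    """

    sets: GeneSetCollection
    n_species: int
    provenance: dict[str, tuple[tuple[str, str], ...]]
    unmapped_count: int
    n_raw_genes: int = 0
    empty_flagged: frozenset[str] = frozenset()

    @property
    def n_clusters(self) -> int:
        clusters: set[str] = set()
        for gs in self.sets:
            clusters |= gs.members
        return len(clusters)

    @property
    def n_edges(self) -> int:
        return self.sets.n_edges()

    def summary(self) -> dict[str, int]:
        return {
            "n_sets": len(self.sets),
            "n_species": self.n_species,
            "n_raw_genes": self.n_raw_genes,
            "n_clusters": self.n_clusters,
            "n_edges": self.n_edges,
            "unmapped_count": self.unmapped_count,
        }

    def with_sets(self, sets: GeneSetCollection,
                  empty_flagged: frozenset[str] = frozenset()) -> "HarmonizedCollection":
        """Same identifier space, different set contents (bootstrap resamples)."""
        return HarmonizedCollection(
            sets=sets,
            n_species=self.n_species,
            provenance=self.provenance,
            unmapped_count=self.unmapped_count,
            n_raw_genes=self.n_raw_genes,
            empty_flagged=empty_flagged,
        )


def harmonize(collection: GeneSetCollection, hmap: HomologyMap) -> HarmonizedCollection:
    """Replace every member of every set by its homology-cluster id.

    A member with no homology entry is kept as its own singleton cluster
    ``solo:<species>:<gene_id>`` rather than dropped, so within-species
    intersections survive incomplete homology coverage.  Duplicates created
    by the mapping (two in-species paralogs in one cluster) are collapsed.
    """
    provenance: dict[str, set[tuple[str, str]]] = {}
    raw_pairs: set[tuple[str, str]] = set()
    unmapped_pairs: set[tuple[str, str]] = set()
    harmonized = GeneSetCollection()
    for gs in collection:
        mapped: set[str] = set()
        for gene in gs.members:
            pair = (gs.species, gene)
            raw_pairs.add(pair)
            cluster = hmap.get(gs.species, gene)
            if cluster is None:
                cluster = f"solo:{gs.species}:{gene}"
                unmapped_pairs.add(pair)
            mapped.add(cluster)
            provenance.setdefault(cluster, set()).add(pair)
        harmonized.add(replace(gs, members=frozenset(mapped), universe=None))
    hc = HarmonizedCollection(
        sets=harmonized,
        n_species=len(collection.species()),
        provenance={c: tuple(sorted(p)) for c, p in sorted(provenance.items())},
        unmapped_count=len(unmapped_pairs),
        n_raw_genes=len(raw_pairs),
    )
    logger.info(
        "harmonized %d sets: %d raw genes -> %d clusters, %d edges, %d unmapped",
        len(harmonized), hc.n_raw_genes, hc.n_clusters, hc.n_edges, hc.unmapped_count,
    )
    return hc
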