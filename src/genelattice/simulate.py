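"""Synthetic multi-species gene-set corpora with planted signal.

The generator emulates the structure of a curated cross-species gene-set
corpus: a handful of species, a few dozen sets with heavy-tailed
(lognormal) sizes, homology clusters that cover only part of the species
panel, a small number of planted high-degree genes recurring across
species, and a curated "known genes" list that deliberately omits one
planted gene — the designated novel candidate the pipeline should surface.

Everything is deterministic from the seed, and the returned
:class:`GroundTruth` records exactly what was planted so recovery can be
asserted rather than eyeballed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .errors import GeneLatticeError
from .genesets import (
    GeneSet,
    GeneSetCollection,
    HomologyMap,
    write_gmt,
    write_homology_map,
)

__all__ = ["GeneratorConfig", "GroundTruth", "generate_homology_map",
           "generate_collection", "emit_fixture"]

SPECIES_PANEL = ("Dm", "Dr", "Hs", "Mm", "Rn")


@dataclass(frozen=True)
class GeneratorConfig:
    """Corpus shape parameters.

    Defaults emulate a 32-set, five-species alcohol-style corpus scaled to a
    pool of 800 homology clusters: lognormal set sizes averaging ~40
    clusters, 6 planted genes each present in 9 of 32 sets (28% of sets)
    across at least four species, and a known list containing every planted
    gene but one.  ``species_coverage_prob`` = 0.26 makes a cluster carry
    about two species-specific genes on average across five species
    (one anchor species always covered, each other species with prob 0.26).
    """

    seed: int = 0
    n_species: int = 5
    n_sets: int = 32
    n_clusters: int = 800
    set_size_log_mean: float = 3.3
    set_size_log_sd: float = 0.9
    n_planted: int = 6
    planted_degree: int = 9
    known_fraction: float | None = None  # None -> all planted but one
    n_known_background: int = 50
    species_coverage_prob: float = 0.26
    strict_separation: bool = True

    def __post_init__(self) -> None:
        if self.n_planted < 1:
            raise GeneLatticeError("n_planted must be >= 1")
        if self.planted_degree > self.n_sets:
            raise GeneLatticeError("planted_degree cannot exceed n_sets")
        if not 0 <= self.species_coverage_prob <= 1:
            raise GeneLatticeError("species_coverage_prob must be in [0, 1]")
        if self.known_fraction is not None and not 0 <= self.known_fraction <= 1:
            raise GeneLatticeError("known_fraction must be in [0, 1]")

    @property
    def species(self) -> tuple[str, ...]:
        if self.n_species <= len(SPECIES_PANEL):
            return SPECIES_PANEL[: self.n_species]
        extra = tuple(f"Sp{i}" for i in range(len(SPECIES_PANEL), self.n_species))
        return SPECIES_PANEL + extra


@dataclass
class GroundTruth:
    """What was planted, for closed-loop testing."""

    planted: dict[str, dict[str, int]]  # cluster id -> {"degree", "n_species"}
    designated_novel: str
    known_list: list[str]

    def __post_init__(self) -> None:
        assert self.designated_novel not in self.known_list


def _cluster_id(i: int) -> str:
    return f"HC{i:05d}"


def _gene_id(i: int, species: str) -> str:
    return f"g{i}_{species}"


def generate_homology_map(
    config: GeneratorConfig, rng: np.random.Generator
) -> HomologyMap:
    """Homology clusters with partial species coverage.

    Each cluster always covers one anchor species (round-robin, so coverage
    is balanced) and each remaining species independently with probability
    ``species_coverage_prob`` — every cluster is covered somewhere by
    construction, and non-anchor cells are exact Bernoulli draws.
    """
    species = config.species
    hmap = HomologyMap()
    draws = rng.random((config.n_clusters, len(species)))
    for i in range(config.n_clusters):
        anchor = species[i % len(species)]
        for j, sp in enumerate(species):
            if sp == anchor or draws[i, j] < config.species_coverage_prob:
                hmap.add(_cluster_id(i), sp, _gene_id(i, sp))
    return hmap


def _choose_planted_sets(
    config: GeneratorConfig,
    species_of_set: list[str],
    rng: np.random.Generator,
) -> list[int]:
    """Pick planted_degree set indices spanning >= min(4, n_species) species."""
    want_species = min(4, config.n_species, config.planted_degree)
    by_species: dict[str, list[int]] = {}
    for idx, sp in enumerate(species_of_set):
        by_species.setdefault(sp, []).append(idx)
    span = [
        str(s)
        for s in rng.choice(sorted(by_species), size=want_species, replace=False)
    ]
    chosen = [int(rng.choice(by_species[sp])) for sp in span]
    remaining = sorted(set(range(config.n_sets)) - set(chosen))
    extra = config.planted_degree - len(chosen)
    if extra > 0:
        chosen += [int(i) for i in rng.choice(remaining, size=extra, replace=False)]
    return sorted(chosen)


def generate_collection(
    config: GeneratorConfig,
) -> tuple[GeneSetCollection, HomologyMap, GroundTruth]:
    """Generate the corpus, its homology map and the ground truth.

    Sets are assigned species round-robin; background members are sampled
    without replacement from the clusters covered in the set's species
    (planted clusters excluded, so planted degrees are exact).  Planted
    clusters are made fully covered across species — conserved genes —
    and inserted into their chosen sets post-hoc.  With
    ``strict_separation`` background cluster reuse is capped at
    planted_degree - 1 sets, so no background gene can tie a planted one.
    """
    rng = np.random.default_rng(config.seed)
    species = config.species
    hmap = generate_homology_map(config, rng)

    planted_idx = sorted(
        int(i) for i in rng.choice(config.n_clusters, size=config.n_planted, replace=False)
    )
    planted_clusters = [_cluster_id(i) for i in planted_idx]
    for i in planted_idx:  # conserved across the whole panel
        for sp in species:
            hmap.add(_cluster_id(i), sp, _gene_id(i, sp))

    species_of_set = [species[k % len(species)] for k in range(config.n_sets)]
    # background pool per species: clusters covered there, excluding planted
    covered: dict[str, list[str]] = {sp: [] for sp in species}
    for i in range(config.n_clusters):
        cid = _cluster_id(i)
        if cid in planted_clusters:
            continue
        for sp in species:
            if hmap.get(sp, _gene_id(i, sp)) is not None:
                covered[sp].append(cid)
    pool_by_species = {sp: sorted(c) for sp, c in covered.items()}

    sizes = np.ceil(
        rng.lognormal(config.set_size_log_mean, config.set_size_log_sd, config.n_sets)
    ).astype(int)
    usage: dict[str, int] = {}
    members_by_set: list[set[str]] = []
    cap = config.planted_degree - 1 if config.strict_separation else None
    for k in range(config.n_sets):
        sp = species_of_set[k]
        pool = pool_by_species[sp]
        if cap is not None:
            pool = [c for c in pool if usage.get(c, 0) < cap]
        size = int(min(max(sizes[k], 2), len(pool)))
        chosen = {str(c) for c in rng.choice(pool, size=size, replace=False)}
        for c in chosen:
            usage[c] = usage.get(c, 0) + 1
        members_by_set.append(chosen)

    planted_info: dict[str, dict[str, int]] = {}
    for cid in planted_clusters:
        target_sets = _choose_planted_sets(config, species_of_set, rng)
        for k in target_sets:
            members_by_set[k].add(cid)
        planted_info[cid] = {
            "degree": len(target_sets),
            "n_species": len({species_of_set[k] for k in target_sets}),
        }

    collection = GeneSetCollection()
    for k in range(config.n_sets):
        sp = species_of_set[k]
        raw_members = frozenset(
            _gene_id(int(c[2:]), sp) for c in members_by_set[k]
        )
        collection.add(
            GeneSet(
                set_id=f"GS{k:03d}",
                label=f"synthetic {sp} set {k}",
                species=sp,
                tier="III" if k % 2 == 0 else "IV",
                members=raw_members,
            )
        )

    novel_pos = int(rng.integers(config.n_planted))
    designated_novel = planted_clusters[novel_pos]
    if config.known_fraction is None:
        known_planted = [c for c in planted_clusters if c != designated_novel]
    else:
        n_known = int(round(config.known_fraction * config.n_planted))
        candidates = [c for c in planted_clusters if c != designated_novel]
        known_planted = candidates[: min(n_known, len(candidates))]
    used_background = sorted(
        {c for ms in members_by_set for c in ms} - set(planted_clusters)
    )
    n_bg = min(config.n_known_background, len(used_background))
    known_background = sorted(
        str(c) for c in rng.choice(used_background, size=n_bg, replace=False)
    )
    known_list = sorted(set(known_planted) | set(known_background))
    truth = GroundTruth(
        planted=planted_info,
        designated_novel=designated_novel,
        known_list=known_list,
    )
    return collection, hmap, truth


def known_genes_collection(
    truth: GroundTruth, hmap: HomologyMap
) -> GeneSetCollection:
    """Express the known-gene clusters as species-specific curated sets
    (one set per species, each member written in a species it covers)."""
    buckets: dict[str, set[str]] = {}
    for cid in truth.known_list:
        entries = hmap.members_of(cid)
        sp, gene = entries[0]  # deterministic: first covered species
        buckets.setdefault(sp, set()).add(gene)
    collection = GeneSetCollection()
    for sp in sorted(buckets):
        collection.add(
            GeneSet(
                set_id=f"KNOWN_{sp}",
                label=f"curated known genes ({sp})",
                species=sp,
                tier="I",
                members=frozenset(buckets[sp]),
            )
        )
    return collection


def emit_fixture(config: GeneratorConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write sets.gmt, homology.tsv, known.gmt and truth.json to *out_dir*."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    collection, hmap, truth = generate_collection(config)
    paths = {
        "sets": write_gmt(collection, out_dir / "sets.gmt"),
        "homology": write_homology_map(hmap, out_dir / "homology.tsv"),
        "known": write_gmt(known_genes_collection(truth, hmap), out_dir / "known.gmt"),
        "truth": out_dir / "truth.json",
    }
    truth_doc = {
        "designated_novel": truth.designated_novel,
        "known_list": truth.known_list,
        "planted": truth.planted,
        "config": asdict(config),
    }
    paths["truth"].write_text(
        json.dumps(truth_doc, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return paths


def fixture_digest(paths: dict[str, Path]) -> str:
    """SHA-256 over the emitted files, for determinism checks."""
    h = hashlib.sha256()
    for name in sorted(paths):
        h.update(paths[name].read_bytes())
    return h.hexdigest()
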