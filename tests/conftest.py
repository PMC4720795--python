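import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from genelattice.bipartite import BipartiteGraph

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_graph(genes_of_set: dict[str, set[str]],
               species: dict[str, str] | None = None) -> BipartiteGraph:
    """Build a BipartiteGraph from plain dicts, defaulting species to Mm."""
    species = species or {s: "Mm" for s in genes_of_set}
    empty = frozenset(s for s, g in genes_of_set.items() if not g)
    return BipartiteGraph(
        {s: frozenset(g) for s, g in genes_of_set.items()}, species, empty_flagged=empty
    )


def random_graph(rng: np.random.Generator, max_sets: int = 12,
                 max_genes: int = 30) -> BipartiteGraph:
    """A random incidence graph with edge density drawn from [0.1, 0.6];
    genes with no memberships are dropped, empty sets flagged."""
    n_sets = int(rng.integers(1, max_sets + 1))
    n_genes = int(rng.integers(1, max_genes + 1))
    density = rng.uniform(0.1, 0.6)
    incidence = rng.random((n_genes, n_sets)) < density
    genes_of_set = {
        f"S{j:02d}": {f"g{i:02d}" for i in range(n_genes) if incidence[i, j]}
        for j in range(n_sets)
    }
    species_pool = ["Mm", "Hs", "Rn", "Dm", "Dr"]
    species = {s: species_pool[k % 5] for k, s in enumerate(sorted(genes_of_set))}
    return make_graph(genes_of_set, species)


@pytest.fixture
def worked_three_sets() -> BipartiteGraph:
    """A={1,2,3}, B={2,3,4}, C={3,4,5}: the canonical 6-node hierarchy."""
    return make_graph({"A": {"1", "2", "3"}, "B": {"2", "3", "4"}, "C": {"3", "4", "5"}})


@pytest.fixture
def two_set_overlap() -> BipartiteGraph:
    """A={g1,g2,g3}, B={g2,g3,g4}: three maximal bicliques."""
    return make_graph({"A": {"g1", "g2", "g3"}, "B": {"g2", "g3", "g4"}})
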