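"""Hierarchy assembly: node closure, Hasse covers, emphasis, cohesiveness."""

import networkx as nx
import numpy as np
import pytest

from genelattice import (
    build_hierarchy,
    cohesiveness_summary,
    emphasis_depth_profile,
    mark_emphasis,
)
from conftest import make_graph, random_graph


def sigs(h):
    return {tuple(sorted(s)) for s in h.nodes}


def edges(h):
    return {(tuple(sorted(p)), tuple(sorted(c))) for p, c in h.edges}


def brute_force_nodes(graph):
    """Oracle: every closed set-group with non-empty intersection, plus all
    singletons, by exhaustive iteration over the power set."""
    from itertools import combinations

    set_ids = list(graph.set_vertices)
    out = {frozenset([s]) for s in set_ids}
    for r in range(1, len(set_ids) + 1):
        for group in combinations(set_ids, r):
            inter = frozenset.intersection(*(graph.genes_of(s) for s in group))
            if not inter:
                continue
            closure = frozenset(
                s for s in set_ids if inter <= graph.genes_of(s)
            )
            if closure == frozenset(group):
                out.add(frozenset(group))
    return out


def transitive_reduction_edges(node_sigs):
    """Oracle: containment order minus transitive edges, via networkx."""
    dg = nx.DiGraph()
    dg.add_nodes_from(node_sigs)
    for p in node_sigs:
        for c in node_sigs:
            if c < p:
                dg.add_edge(p, c)
    return set(nx.transitive_reduction(dg).edges())


class TestWorkedThreeSetCase:
    def test_exact_node_set(self, worked_three_sets):
        h = build_hierarchy(worked_three_sets)
        assert sigs(h) == {
            ("A",), ("B",), ("C",), ("A", "B"), ("B", "C"), ("A", "B", "C"),
        }
        assert ("A", "C") not in sigs(h)  # not closed: cl({A,C}) = {A,B,C}
        assert h.nodes[frozenset({"A", "B"})].genes == {"2", "3"}
        assert h.nodes[frozenset({"B", "C"})].genes == {"3", "4"}
        assert h.nodes[frozenset({"A", "B", "C"})].genes == {"3"}

    def test_exact_cover_edges(self, worked_three_sets):
        h = build_hierarchy(worked_three_sets)
        assert edges(h) == {
            (("A", "B", "C"), ("A", "B")),
            (("A", "B", "C"), ("B", "C")),
            (("A", "B"), ("A",)),
            (("A", "B"), ("B",)),
            (("B", "C"), ("B",)),
            (("B", "C"), ("C",)),
        }
        # {A,B,C} -> {C} is transitive through {B,C}, hence absent
        assert (("A", "B", "C"), ("C",)) not in edges(h)


def test_disjoint_sets_are_isolated_terminals():
    h = build_hierarchy(make_graph({"A": {"g1"}, "B": {"g2"}}))
    assert sigs(h) == {("A",), ("B",)}
    assert h.edges == []


def test_contained_set_still_gets_forced_terminal():
    # A subset of B: {A} is not closed but must exist as a terminal
    h = build_hierarchy(make_graph({"A": {"g1", "g2"}, "B": {"g1", "g2", "g3"}}))
    assert sigs(h) == {("A",), ("B",), ("A", "B")}
    assert h.nodes[frozenset({"A", "B"})].genes == {"g1", "g2"}
    assert edges(h) == {(("A", "B"), ("A",)), (("A", "B"), ("B",))}


def test_empty_flagged_set_is_terminal_only():
    h = build_hierarchy(make_graph({"A": {"g1"}, "B": set()}))
    assert sigs(h) == {("A",), ("B",)}
    assert h.nodes[frozenset({"B"})].genes == frozenset()


def test_nodes_match_brute_force_on_random_instances():
    rng = np.random.default_rng(23)
    for _ in range(40):
        g = random_graph(rng, max_sets=8, max_genes=18)
        h = build_hierarchy(g)
        assert set(h.nodes) == brute_force_nodes(g)


def test_edges_match_transitive_reduction_oracle():
    rng = np.random.default_rng(29)
    for _ in range(40):
        g = random_graph(rng, max_sets=8, max_genes=18)
        h = build_hierarchy(g)
        assert set(h.edges) == transitive_reduction_edges(set(h.nodes))


def test_gene_payload_antimonotone_along_edges():
    rng = np.random.default_rng(31)
    for _ in range(40):
        g = random_graph(rng, max_sets=10, max_genes=25)
        h = build_hierarchy(g)
        for parent, child in h.edges:
            assert h.nodes[parent].genes <= h.nodes[child].genes


def test_every_biclique_is_a_node():
    from genelattice import enumerate_maximal_bicliques

    rng = np.random.default_rng(37)
    for _ in range(20):
        g = random_graph(rng, max_sets=8, max_genes=15)
        h = build_hierarchy(g)
        for b in enumerate_maximal_bicliques(g):
            assert b.set_group in h.nodes
            assert h.nodes[b.set_group].genes == b.gene_group


class TestEmphasis:
    def test_empty_emphasis_flags_nothing(self, worked_three_sets):
        h = mark_emphasis(build_hierarchy(worked_three_sets), [])
        assert not any(n.emphasis_hit for n in h.nodes.values())

    def test_full_emphasis_flags_everything(self, worked_three_sets):
        h = build_hierarchy(worked_three_sets)
        all_genes = set().union(*(n.genes for n in h.nodes.values()))
        h = mark_emphasis(h, all_genes)
        assert all(n.emphasis_hit for n in h.nodes.values())

    def test_single_gene_emphasis_flags_exact_nodes(self, worked_three_sets):
        h = mark_emphasis(build_hierarchy(worked_three_sets), {"2"})
        flagged = {tuple(sorted(s)) for s, n in h.nodes.items() if n.emphasis_hit}
        assert flagged == {("A",), ("B",), ("A", "B")}
        assert h.nodes[frozenset({"A", "B"})].emphasis_genes_present == {"2"}

    def test_depth_profile_counts(self, worked_three_sets):
        h = mark_emphasis(build_hierarchy(worked_three_sets), {"2"})
        profile = emphasis_depth_profile(h)
        assert profile["per_level"] == {1: (3, 2), 2: (2, 1), 3: (1, 0)}
        assert profile["max_level"] == 3
        assert profile["max_flagged_level"] == 2

    def test_depth_profile_all_unflagged(self, worked_three_sets):
        h = mark_emphasis(build_hierarchy(worked_three_sets), [])
        profile = emphasis_depth_profile(h)
        assert all(f == 0 for _, f in profile["per_level"].values())
        assert profile["max_flagged_level"] == 0


class TestCohesiveness:
    def test_worked_case(self, worked_three_sets):
        h = build_hierarchy(worked_three_sets)
        s = cohesiveness_summary(h, n_sets=3, min_genes=2)
        assert s["possible"] == 4
        assert s["populated"] == 3
        assert s["populated_gt_min"] == 0  # payloads have at most 2 genes

    def test_single_set_degenerate(self):
        h = build_hierarchy(make_graph({"A": {"g1"}}))
        s = cohesiveness_summary(h, n_sets=1, min_genes=1)
        assert s["possible"] == 0
        assert s["populated"] == 0

    def test_min_genes_must_be_positive(self, worked_three_sets):
        h = build_hierarchy(worked_three_sets)
        with pytest.raises(ValueError):
            cohesiveness_summary(h, n_sets=3, min_genes=0)
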