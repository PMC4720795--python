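"""Serialization of the gene-set graph view and similarity hierarchies.

Two structures are exported: the degree-thresholded bipartite "gene-set
graph" view (genes ordered by ascending connectivity, mirroring the
low-degree-left / high-degree-right display convention) and the
(optionally bootstrapped) similarity hierarchy.  Formats: GraphML (via
networkx), DOT and a JSON dialect that round-trips losslessly.  Element
ordering is deterministic so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .bipartite import BipartiteGraph
from .bootstrap import ConsensusGraph
from .errors import GeneLatticeError
from .hierarchy import HierarchyGraph

__all__ = [
    "GeneSetGraphView",
    "build_geneset_graph_view",
    "to_networkx",
    "export_graph",
    "load_graph_json",
    "FORMATS",
]

FORMATS = ("graphml", "dot", "json")
DEFAULT_DEGREE_THRESHOLD = 2


@dataclass
class GeneSetGraphView:
    """Degree-thresholded bipartite view with a display ordering on genes."""

    graph: BipartiteGraph
    threshold: int
    retained_genes: tuple[str, ...]  # ascending degree, ties lexicographic

    @property
    def rank_of_gene(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.retained_genes, start=1)}


def build_geneset_graph_view(
    graph: BipartiteGraph, threshold: int = DEFAULT_DEGREE_THRESHOLD
) -> GeneSetGraphView:
    """Drop genes with degree below *threshold*; order survivors by
    ascending degree then id (display rank: low-degree left)."""
    if threshold < 1:
        raise GeneLatticeError("threshold must be >= 1")
    retained = tuple(
        sorted(
            (g for g in graph.gene_vertices if graph.gene_degree(g) >= threshold),
            key=lambda g: (graph.gene_degree(g), g),
        )
    )
    return GeneSetGraphView(graph=graph, threshold=threshold, retained_genes=retained)


def _sig_id(sig: frozenset[str]) -> str:
    return "+".join(sorted(sig))


def to_networkx(obj: GeneSetGraphView | HierarchyGraph | ConsensusGraph) -> nx.Graph:
    """Convert an exportable structure to a networkx graph with attributes.

    Hierarchies become DiGraphs (edges parent->child, ``level`` per node,
    ``genes`` as a ';'-joined payload, emphasis flags, and bootstrap
    frequencies when present); views become bipartite Graphs with a
    ``rank`` display attribute on retained genes.
    """
    if isinstance(obj, GeneSetGraphView):
        g = nx.Graph()
        for s in obj.graph.set_vertices:
            g.add_node(
                f"set:{s}", kind="set", species=obj.graph.species_of_set[s]
            )
        for gene in obj.retained_genes:
            g.add_node(
                f"gene:{gene}",
                kind="gene",
                degree=obj.graph.gene_degree(gene),
                rank=obj.rank_of_gene[gene],
            )
        for gene in obj.retained_genes:
            for s in sorted(obj.graph.sets_of(gene)):
                g.add_edge(f"gene:{gene}", f"set:{s}")
        g.graph["threshold"] = obj.threshold
        return g

    if isinstance(obj, ConsensusGraph):
        h, node_freq, edge_freq = obj.retained, obj.node_freq, obj.edge_freq
    else:
        h, node_freq, edge_freq = obj, None, None

    dg = nx.DiGraph()
    for sig, node in h.nodes.items():
        attrs = {
            "level": node.level,
            "is_terminal": node.is_terminal,
            "genes": ";".join(sorted(node.genes)),
            "n_genes": len(node.genes),
            "emphasis_hit": node.emphasis_hit,
            "color": "blue" if node.emphasis_hit else "white",
        }
        if node.emphasis_genes_present:
            attrs["emphasis_genes"] = ";".join(sorted(node.emphasis_genes_present))
        if node_freq is not None:
            attrs["bootstrap_freq"] = round(node_freq.get(sig, 0.0), 6)
        dg.add_node(_sig_id(sig), **attrs)
    for parent, child in h.edges:
        attrs = {}
        if edge_freq is not None:
            attrs["bootstrap_freq"] = round(edge_freq.get((parent, child), 0.0), 6)
        dg.add_edge(_sig_id(parent), _sig_id(child), **attrs)
    return dg


def _dot_escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def _to_dot(g: nx.Graph) -> str:
    directed = g.is_directed()
    lines = ["digraph G {" if directed else "graph G {"]
    arrow = "->" if directed else "--"
    for node in sorted(g.nodes):
        attrs = g.nodes[node]
        attr_str = ", ".join(
            f'{k}="{_dot_escape(str(v))}"' for k, v in sorted(attrs.items())
        )
        lines.append(f'  "{_dot_escape(node)}" [{attr_str}];')
    edges = g.edges(data=True)
    edge_list = sorted((u, v, tuple(sorted(d.items()))) for u, v, d in edges)
    for u, v, data in edge_list:
        attr_str = ", ".join(f'{k}="{_dot_escape(str(val))}"' for k, val in data)
        suffix = f" [{attr_str}]" if attr_str else ""
        lines.append(f'  "{_dot_escape(u)}" {arrow} "{_dot_escape(v)}"{suffix};')
    lines.append("}")
    return "\n".join(lines) + "\n"


def _to_json_doc(g: nx.Graph) -> dict:
    return {
        "directed": g.is_directed(),
        "graph": {k: g.graph[k] for k in sorted(g.graph)},
        "nodes": [
            {"id": n, **{k: v for k, v in sorted(g.nodes[n].items())}}
            for n in sorted(g.nodes)
        ],
        "edges": [
            {"source": u, "target": v, **dict(data)}
            for u, v, data in sorted(
                (u, v, tuple(sorted(d.items()))) for u, v, d in g.edges(data=True)
            )
        ],
    }


def export_graph(
    obj: GeneSetGraphView | HierarchyGraph | ConsensusGraph | nx.Graph,
    format: str,
    path: str | Path,
) -> Path:
    """Write *obj* to *path* in ``graphml``, ``dot`` or ``json`` format."""
    if format not in FORMATS:
        raise GeneLatticeError(f"unknown format {format!r}; expected one of {FORMATS}")
    g = obj if isinstance(obj, nx.Graph) else to_networkx(obj)
    path = Path(path)
    if format == "graphml":
        # sort elements for byte-stable output
        ordered = nx.DiGraph() if g.is_directed() else nx.Graph()
        ordered.graph.update({k: g.graph[k] for k in sorted(g.graph)})
        for n in sorted(g.nodes):
            ordered.add_node(n, **{k: g.nodes[n][k] for k in sorted(g.nodes[n])})
        for u, v, d in sorted(g.edges(data=True)):
            ordered.add_edge(u, v, **{k: d[k] for k in sorted(d)})
        nx.write_graphml(ordered, path)
    elif format == "dot":
        path.write_text(_to_dot(g), encoding="utf-8")
    else:
        path.write_text(
            json.dumps(_to_json_doc(g), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
    return path


def load_graph_json(path: str | Path) -> nx.Graph:
    """Parse a JSON export back into a networkx graph (round-trip inverse)."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    g = nx.DiGraph() if doc["directed"] else nx.Graph()
    g.graph.update(doc.get("graph", {}))
    for node in doc["nodes"]:
        attrs = {k: v for k, v in node.items() if k != "id"}
        g.add_node(node["id"], **attrs)
    for edge in doc["edges"]:
        attrs = {k: v for k, v in edge.items() if k not in ("source", "target")}
        g.add_edge(edge["source"], edge["target"], **attrs)
    return g
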