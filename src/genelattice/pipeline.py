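"""One-call reproduction of the full analysis flow.

harmonize -> incidence -> hierarchy -> bootstrap consensus -> emphasis
marking -> cohesiveness / depth summaries -> prioritization -> exports,
with a manifest (parameter echo, input checksums, output checksums, stage
timings) sufficient to reproduce the run bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .algebra import derive_known_genes
from .bipartite import build_incidence
from .bootstrap import BootstrapParams, bootstrap_consensus
from .errors import PipelineStageError
from .export import build_geneset_graph_view, export_graph
from .genesets import read_gmt, read_homology_map, harmonize
from .hierarchy import (
    build_hierarchy,
    cohesiveness_summary,
    emphasis_depth_profile,
    mark_emphasis,
)
from .prioritize import novel_gene_report, rank_genes, report_to_json, report_to_tsv

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs, parameters and output location for one pipeline run."""

    sets_path: str
    homology_path: str
    out_dir: str
    seed: int
    known_path: str | None = None
    bootstrap: BootstrapParams | None = None  # defaults derived from seed
    gene_degree_threshold: int = 2
    min_genes: int = 2
    top_k: int = 10
    export_formats: tuple[str, ...] = ("graphml", "dot", "json")

    def resolved_bootstrap(self) -> BootstrapParams:
        return self.bootstrap or BootstrapParams(seed=self.seed)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(doc: dict, path: Path) -> Path:
    path.write_text(json.dumps(doc, indent=2, sort_keys=True, default=str) + "\n",
                    encoding="utf-8")
    return path


class _Stage:
    """Context manager that names the failing stage and records timing."""

    def __init__(self, name: str, timings: dict[str, float]):
        self.name = name
        self.timings = timings

    def __enter__(self):
        logger.info("stage %s: start", self.name)
        self._t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        self.timings[self.name] = round(time.perf_counter() - self._t0, 4)
        if exc is not None and not isinstance(exc, PipelineStageError):
            raise PipelineStageError(self.name, exc) from exc
        logger.info("stage %s: done in %.3fs", self.name, self.timings[self.name])
        return False


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full flow and return the manifest (also written to disk)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    outputs: dict[str, Path] = {}
    params = config.resolved_bootstrap()

    inputs = {"sets": Path(config.sets_path), "homology": Path(config.homology_path)}
    if config.known_path:
        inputs["known"] = Path(config.known_path)

    with _Stage("harmonize", timings):
        for name, p in inputs.items():
            if not p.exists():
                raise FileNotFoundError(f"{name} input not found: {p}")
        collection = read_gmt(inputs["sets"])
        hmap = read_homology_map(inputs["homology"])
        hc = harmonize(collection, hmap)
        outputs["harmonization_summary"] = _write_json(
            hc.summary(), out_dir / "harmonization_summary.json"
        )

    with _Stage("incidence", timings):
        graph = build_incidence(hc)

    with _Stage("hierarchy", timings):
        hierarchy = build_hierarchy(graph)

    with _Stage("emphasis", timings):
        if config.known_path:
            known = derive_known_genes(read_gmt(inputs["known"]), hmap)
        else:
            from .genesets import GeneSet

            known = GeneSet(set_id="known_genes", tier="I", members=frozenset())
        hierarchy = mark_emphasis(hierarchy, known.members)
        profile = emphasis_depth_profile(hierarchy)
        outputs["emphasis_profile"] = _write_json(
            {
                "per_level": {str(k): list(v) for k, v in profile["per_level"].items()},
                "max_level": profile["max_level"],
                "max_flagged_level": profile["max_flagged_level"],
            },
            out_dir / "emphasis_profile.json",
        )

    with _Stage("cohesiveness", timings):
        outputs["cohesiveness"] = _write_json(
            cohesiveness_summary(hierarchy, len(graph.set_vertices), config.min_genes),
            out_dir / "cohesiveness.json",
        )

    with _Stage("bootstrap", timings):
        consensus = bootstrap_consensus(hc, params)
        consensus.retained = mark_emphasis(consensus.retained, known.members)
        outputs["bootstrap_summary"] = _write_json(
            consensus.summary(), out_dir / "bootstrap_summary.json"
        )

    with _Stage("prioritize", timings):
        records = rank_genes(graph, known)
        outputs["priorities_tsv"] = report_to_tsv(records, out_dir / "priorities.tsv")
        outputs["priorities_json"] = report_to_json(records, out_dir / "priorities.json")
        report = novel_gene_report(records, top_k=config.top_k)
        outputs["novel_report"] = _write_json(report, out_dir / "novel_genes.json")

    with _Stage("export", timings):
        view = build_geneset_graph_view(graph, config.gene_degree_threshold)
        for fmt in config.export_formats:
            outputs[f"hierarchy_{fmt}"] = export_graph(
                hierarchy, fmt, out_dir / f"result.hierarchy.{fmt}"
            )
            outputs[f"bootstrap_hierarchy_{fmt}"] = export_graph(
                consensus, fmt, out_dir / f"result.hierarchy_bootstrap.{fmt}"
            )
            outputs[f"geneset_graph_{fmt}"] = export_graph(
                view, fmt, out_dir / f"result.geneset_graph.{fmt}"
            )

    manifest = {
        "genelattice_version": __version__,
        "python_version": platform.python_version(),
        "seed": config.seed,
        "parameters": {
            "bootstrap": asdict(params),
            "gene_degree_threshold": config.gene_degree_threshold,
            "min_genes": config.min_genes,
            "top_k": config.top_k,
        },
        "inputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in inputs.items()},
        "outputs": {
            k: {"path": str(p), "sha256": _sha256(p)} for k, p in sorted(outputs.items())
        },
        "counts": {
            **hc.summary(),
            "hierarchy_nodes": hierarchy.n_nodes,
            "hierarchy_edges": hierarchy.n_edges,
            "retained_nodes": consensus.retained.n_nodes,
            "retained_edges": consensus.retained.n_edges,
            "top_novel_gene": report["top_novel_gene"],
        },
        "stage_seconds": timings,
    }
    _write_json(manifest, out_dir / "manifest.json")
    return manifest
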