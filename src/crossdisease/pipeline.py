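"""Pipeline orchestration: simulate -> screen -> overlap -> network -> paths.

A run is described by a flat YAML config with one block per stage.  Stages
execute in a fixed order, each reading only its declared inputs and writing
its outputs under the run's output directory; a manifest records parameter
values, the seed, and a SHA-256 checksum of every output so identical
config + seed reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from . import __version__
from .abma import AbmaParams, results_to_frame, screen_disease
from .evidence_io import (
    read_evidence_table,
    read_gene_list,
    write_evidence_table,
    write_gene_list,
    write_results,
)
from .network_analysis import build_graph, centralities, select_hubs, topology_metrics
from .overlap_stats import overlap_report
from .pathway_builder import (
    find_disease_gene_disease_paths,
    pathway_report,
    screen_directional,
    significant_directed_edges,
)
from .synthetic_corpus import SyntheticParams, generate_corpus

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

STAGES = ("simulate", "abma", "overlap", "network", "pathways")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the propagated cause."""


@dataclass
class PipelineConfig:
    """Validated description of a pipeline run."""

    output_dir: Path
    stages: tuple[str, ...] = STAGES
    seed: Optional[int] = None
    evidence_path: Optional[Path] = None
    universe_path: Optional[Path] = None
    edges_path: Optional[Path] = None
    diseases: tuple[str, str] = ("RA", "HNC")
    abma: AbmaParams = field(default_factory=AbmaParams)
    synthetic: Optional[SyntheticParams] = None
    hub_min_metrics: int = 2
    hub_quantile: float = 0.8
    pathway_q_threshold: float = 0.01

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if "simulate" in self.stages and self.seed is None and self.synthetic is None:
            raise ValueError("the simulate stage requires a seed")
        if "simulate" not in self.stages:
            if self.evidence_path is None or not Path(self.evidence_path).exists():
                raise ValueError(
                    f"evidence file not found: {self.evidence_path}"
                )
        for name in ("universe_path", "edges_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{name} does not exist: {p}")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline config into a validated :class:`PipelineConfig`."""
    raw: dict[str, Any] = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    seed = raw.get("seed")
    synthetic = None
    if "synthetic" in raw:
        syn = dict(raw["synthetic"])
        if "diseases" in syn:
            syn["diseases"] = tuple(syn["diseases"])
        if "polarity_null" in syn:
            syn["polarity_null"] = tuple(syn["polarity_null"])
        syn.setdefault("seed", seed if seed is not None else 0)
        synthetic = SyntheticParams(**syn)
    cfg = PipelineConfig(
        output_dir=Path(raw.get("output_dir", "crossdisease_out")),
        stages=tuple(raw.get("stages", STAGES)),
        seed=seed,
        evidence_path=Path(raw["evidence"]) if raw.get("evidence") else None,
        universe_path=Path(raw["universe"]) if raw.get("universe") else None,
        edges_path=Path(raw["edges"]) if raw.get("edges") else None,
        diseases=tuple(raw.get("diseases", ("RA", "HNC"))),
        abma=AbmaParams(**raw.get("abma", {})),
        synthetic=synthetic,
        hub_min_metrics=int(raw.get("network", {}).get("hub_min_metrics", 2)),
        hub_quantile=float(raw.get("network", {}).get("hub_quantile", 0.8)),
        pathway_q_threshold=float(raw.get("pathways", {}).get("q_threshold", 0.01)),
    )
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the enabled stages in order and return the run manifest.

    Outputs land in ``config.output_dir``; the manifest (also written there
    as ``manifest.json``) records the package version, seed, per-stage
    parameters, and a checksum for every file produced.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "parameters": {},
    }
    records = None

    def run_stage(name):
        logger.info("stage %s: start", name)
        try:
            name_fn[name]()
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        logger.info("stage %s: done", name)

    def stage_simulate():
        nonlocal records
        params = config.synthetic or SyntheticParams(seed=config.seed or 0)
        manifest["parameters"]["synthetic"] = dataclasses.asdict(params)
        records, truth = generate_corpus(params)
        write_evidence_table(out / "evidence.tsv", records)
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        outputs["evidence"] = out / "evidence.tsv"
        outputs["truth"] = out / "truth.tsv"
        config.diseases = params.diseases

    def _load_records():
        nonlocal records
        if records is None:
            records = read_evidence_table(config.evidence_path)
        return records

    def stage_abma():
        manifest["parameters"]["abma"] = dataclasses.asdict(config.abma)
        for disease in config.diseases:
            results = screen_disease(_load_records(), disease, config.abma)
            frame = results_to_frame(results)
            path = out / f"abma_{disease}.tsv"
            write_results(path, frame)
            outputs[f"abma_{disease}"] = path

    def _significant_sets() -> dict[str, set[str]]:
        sets = {}
        for disease in config.diseases:
            frame = pd.read_csv(out / f"abma_{disease}.tsv", sep="\t")
            sets[disease] = set(frame.loc[frame["significant"], "gene"])
        return sets

    def stage_overlap():
        disease_a, disease_b = config.diseases
        sets = _significant_sets()
        if config.universe_path is not None:
            universe = read_gene_list(config.universe_path)
        else:  # synthetic runs: the generated gene universe
            universe = sorted({r.gene for r in _load_records()} | set().union(*sets.values()))
        report = overlap_report(sets[disease_a], sets[disease_b], universe)
        payload = {
            "disease_a": disease_a,
            "disease_b": disease_b,
            "universe_n": report.table.universe_n,
            "size_a": report.size_a,
            "size_b": report.size_b,
            "overlap": report.overlap,
            "odds_ratio": report.odds_ratio,
            "p_value": report.p_value,
        }
        (out / "overlap.json").write_text(json.dumps(payload, indent=2) + "\n")
        venn = pd.DataFrame(
            [
                {"region": f"{disease_a}_only", "count": len(report.a_only)},
                {"region": f"{disease_b}_only", "count": len(report.b_only)},
                {"region": "shared", "count": report.overlap},
            ]
        )
        write_results(out / "venn_counts.tsv", venn)
        write_gene_list(out / "shared_genes.txt", report.shared)
        outputs["overlap"] = out / "overlap.json"
        outputs["venn_counts"] = out / "venn_counts.tsv"
        outputs["shared_genes"] = out / "shared_genes.txt"

    def stage_network():
        if config.edges_path is None:
            logger.warning("network stage skipped: no edge list supplied")
            return
        edge_frame = pd.read_csv(config.edges_path, sep="\t")
        g = build_graph(edge_frame.itertuples(index=False))
        metrics = topology_metrics(g)
        (out / "network_metrics.json").write_text(
            json.dumps(dataclasses.asdict(metrics), indent=2) + "\n"
        )
        cent = centralities(g)
        write_results(out / "centralities.tsv", cent)
        hubs = select_hubs(cent, config.hub_min_metrics, config.hub_quantile)
        write_gene_list(out / "hub_genes.txt", hubs)
        import networkx as nx

        nx.write_graphml(g, out / "network.graphml")
        outputs["network_metrics"] = out / "network_metrics.json"
        outputs["centralities"] = out / "centralities.tsv"
        outputs["hub_genes"] = out / "hub_genes.txt"
        outputs["graphml"] = out / "network.graphml"

    def stage_pathways():
        disease_a, disease_b = config.diseases
        recs = _load_records()
        results = []
        for disease in config.diseases:
            results.extend(screen_directional(recs, disease, config.abma))
        edges = significant_directed_edges(results, config.pathway_q_threshold)
        triplets = find_disease_gene_disease_paths(edges, disease_a, disease_b)
        paths, signed = pathway_report(triplets)
        write_results(out / "pathways.tsv", paths)
        write_results(out / "pathway_edges.tsv", signed)
        outputs["pathways"] = out / "pathways.tsv"
        outputs["pathway_edges"] = out / "pathway_edges.tsv"

    name_fn = {
        "simulate": stage_simulate,
        "abma": stage_abma,
        "overlap": stage_overlap,
        "network": stage_network,
        "pathways": stage_pathways,
    }
    if "simulate" not in config.stages:
        _load_records()
    for name in STAGES:
        if name in config.stages:
            run_stage(name)

    manifest["outputs"] = {
        key: {"path": str(p), "sha256": _sha256(p)} for key, p in sorted(outputs.items())
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
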