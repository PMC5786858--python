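"""Config-driven orchestration of the full analysis: load/simulate network,
partition, enrich, select disease and syndrome modules, overlay targets,
run ORA, and write deterministic per-stage artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import yaml

from modenrich.community import Partition, louvain_partition, partition_summary
from modenrich.enrichment import (
    BACKGROUND_POLICIES,
    Background,
    ModuleEnrichment,
    enrich_modules,
    select_disease_modules,
    select_potential_modules,
    select_syndrome_modules,
    whole_graph_background,
)
from modenrich.graph_io import (
    GeneSet,
    WeightedGraph,
    flatten_genes,
    load_bipartite,
    load_gene_sets,
    load_gmt,
    load_string_links,
)
from modenrich.ora import ora
from modenrich.report import Selections, build_report, overlay_targets, write_report
from modenrich.synthetic import SBMSpec, generate_sbm

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised with every validation violation joined into one message."""


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; message names the stage."""


_KNOWN_KEYS = {
    "network",
    "sbm",
    "min_score",
    "strict",
    "seed",
    "resolution",
    "alpha",
    "rr_multiplier",
    "background",
    "disease_genes",
    "symptom_map",
    "targets",
    "gmt",
    "out_dir",
}

_TARGET_KEYS = ("ihd_targets", "bs_formula_targets", "ps_formula_targets")


@dataclass
class PipelineConfig:
    seed: int
    disease_genes: Optional[Path] = None
    network: Optional[Path] = None
    sbm: Optional[SBMSpec] = None
    min_score: int = 700
    strict: bool = True
    resolution: float = 1.0
    alpha: float = 0.01
    rr_multiplier: float = 3.0
    background: str = "covered_modules"
    symptom_map: Optional[Path] = None
    targets: Dict[str, Path] = field(default_factory=dict)
    gmt: Optional[Path] = None
    out_dir: Path = Path("modenrich_out")


def validate_config(source: str | Path | Mapping) -> PipelineConfig:
    """Parse and validate a YAML config (or an already-parsed mapping),
    filling defaults and reporting every violation at once."""
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text(encoding="utf-8"))
    else:
        raw = dict(source)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping of keys to values")

    errors: List[str] = []
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")

    def _path(key: str, required: bool = False) -> Optional[Path]:
        value = raw.get(key)
        if value is None:
            if required:
                errors.append(f"{key}: required path is missing")
            return None
        p = Path(value)
        if not p.exists():
            errors.append(f"{key}: path {p} does not exist")
        return p

    seed = raw.get("seed")
    if not isinstance(seed, int) or isinstance(seed, bool):
        errors.append("seed: an integer seed is required")
        seed = 0

    network = _path("network")
    sbm = None
    if "sbm" in raw:
        try:
            sbm = SBMSpec(**raw["sbm"])
        except (TypeError, ValueError) as exc:
            errors.append(f"sbm: {exc}")
    if (network is None) == (sbm is None):
        errors.append("exactly one of 'network' and 'sbm' must be given")

    min_score = raw.get("min_score", 700)
    if not isinstance(min_score, int) or not 0 <= min_score <= 1000:
        errors.append(f"min_score: must be an integer in [0, 1000], got {min_score!r}")
    alpha = raw.get("alpha", 0.01)
    if not isinstance(alpha, (int, float)) or not 0 < alpha <= 1:
        errors.append(f"alpha: must be in (0, 1], got {alpha!r}")
    rr = raw.get("rr_multiplier", 3.0)
    if not isinstance(rr, (int, float)) or rr < 0:
        errors.append(f"rr_multiplier: must be >= 0, got {rr!r}")
    resolution = raw.get("resolution", 1.0)
    if not isinstance(resolution, (int, float)) or resolution <= 0:
        errors.append(f"resolution: must be > 0, got {resolution!r}")
    background = raw.get("background", "covered_modules")
    if background not in ("covered_modules", "whole_graph"):
        errors.append(
            f"background: must be 'covered_modules' or 'whole_graph', got {background!r}"
        )

    disease_genes = _path("disease_genes", required=True)
    symptom_map = _path("symptom_map")
    gmt = _path("gmt")
    targets: Dict[str, Path] = {}
    for key, value in (raw.get("targets") or {}).items():
        if key not in _TARGET_KEYS:
            errors.append(f"targets: unknown overlay key {key!r}; expected {_TARGET_KEYS}")
            continue
        p = Path(value)
        if not p.exists():
            errors.append(f"targets.{key}: path {p} does not exist")
        targets[key] = p

    if errors:
        raise ConfigError("invalid config:\n  - " + "\n  - ".join(errors))

    return PipelineConfig(
        seed=seed,
        network=network,
        sbm=sbm,
        min_score=min_score,
        strict=bool(raw.get("strict", True)),
        resolution=float(resolution),
        alpha=float(alpha),
        rr_multiplier=float(rr),
        background=background,
        disease_genes=disease_genes,
        symptom_map=symptom_map,
        targets=targets,
        gmt=gmt,
        out_dir=Path(raw.get("out_dir", "modenrich_out")),
    )


def _write_partition(partition: Partition, path: Path) -> None:
    lines = ["node\tmodule"]
    for node in sorted(partition.assignment):
        lines.append(f"{node}\t{partition.assignment[node]}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _write_enrichment(records: List[ModuleEnrichment], path: Path) -> None:
    lines = ["module\tk\tn\tK\tN\tp_value\tproportion\tbackground_proportion"]
    for r in records:
        lines.append(
            f"{r.module}\t{r.input.k}\t{r.input.n}\t{r.input.K}\t{r.input.N}"
            f"\t{r.p_value:.2E}\t{r.proportion:.4f}\t{r.background_proportion:.4f}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute every stage and write artifacts under config.out_dir.

    Returns the run summary (also written as summary.json). On any stage
    failure, partial outputs from this run are removed and a PipelineError
    naming the stage is raised.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    def _emit(name: str, writer, *args) -> Path:
        path = out / name
        writer(*args, path)
        written.append(path)
        return path

    stage = "setup"
    try:
        stage = "network"
        if config.sbm is not None:
            graph, _truth = generate_sbm(config.sbm)
        else:
            graph = load_string_links(
                config.network, min_score=config.min_score, strict=config.strict
            )
        if graph.number_of_edges() == 0:
            raise PipelineError("network stage produced a graph with no edges")
        logger.info(
            "network: %d nodes, %d edges", graph.number_of_nodes(), graph.number_of_edges()
        )

        stage = "partition"
        partition = louvain_partition(graph, seed=config.seed, resolution=config.resolution)
        _emit("partition.tsv", _write_partition, partition)
        sizes = partition_summary(partition)
        logger.info("partition: %d modules, Q=%.4f", len(sizes), partition.modularity)

        stage = "disease_genes"
        gene_sets = load_gene_sets(config.disease_genes, source="disease")
        if not gene_sets:
            raise PipelineError("disease gene file is empty")
        disease = GeneSet(
            name="disease",
            source="disease",
            members=frozenset().union(*(gs.members for gs in gene_sets)),
        )

        stage = "background"
        potential = select_potential_modules(partition, disease)
        if config.background == "covered_modules":
            background = Background(policy="covered_modules", universe=potential.universe)
        else:
            background = whole_graph_background(partition)
        logger.info(
            "background: policy=%s, %d potential modules, universe=%d",
            config.background,
            len(potential.labels),
            len(background.universe),
        )

        stage = "disease_enrichment"
        disease_records = enrich_modules(
            partition, disease, background, alpha=config.alpha,
            rr_multiplier=config.rr_multiplier,
        )
        _emit("disease_enrichment.tsv", _write_enrichment, disease_records)
        selected = select_disease_modules(
            disease_records, alpha=config.alpha, rr_multiplier=config.rr_multiplier
        )
        disease_labels = [r.module for r in selected]
        logger.info(
            "disease modules: %d of %d records (K=%d, background=%.4f)",
            len(selected),
            len(disease_records),
            disease_records[0].input.K if disease_records else 0,
            disease_records[0].background_proportion if disease_records else 0.0,
        )

        stage = "symptom_enrichment"
        symptom_records: List[ModuleEnrichment] = []
        syndrome_labels: List[int] = []
        if config.symptom_map is not None:
            bmap = load_bipartite(config.symptom_map)
            symptoms = GeneSet(
                name="symptoms", source="symptom", members=flatten_genes(bmap)
            )
            symptom_records = enrich_modules(
                partition, symptoms, background, alpha=config.alpha,
                rr_multiplier=config.rr_multiplier,
            )
            _emit("symptom_enrichment.tsv", _write_enrichment, symptom_records)
            syndrome = select_syndrome_modules(
                symptom_records, disease_labels, alpha=config.alpha
            )
            syndrome_labels = [r.module for r in syndrome]
            logger.info("syndrome modules: %d", len(syndrome_labels))

        stage = "target_overlay"
        overlays: Dict[str, Dict[int, int]] = {}
        for key, path in config.targets.items():
            tsets = load_gene_sets(path, source="target_drug")
            members = frozenset().union(*(t.members for t in tsets)) if tsets else frozenset()
            tset = GeneSet(name=key, source="target_drug", members=members)
            overlays[key] = overlay_targets(partition, tset, disease_labels)

        stage = "report"
        if disease_labels:
            rows = build_report(
                disease_records,
                symptom_records,
                overlays,
                Selections(disease=disease_labels, syndrome=syndrome_labels),
            )
            path = out / "report.tsv"
            write_report(rows, path, format="tsv")
            written.append(path)
            path = out / "report.json"
            write_report(rows, path, format="json")
            written.append(path)

        stage = "ora"
        if config.gmt is not None and disease_labels:
            collection = load_gmt(config.gmt)
            groups = partition.modules()
            for label in disease_labels:
                query = GeneSet(
                    name=f"module_{label}", source="disease", members=groups[label]
                )
                gmt_universe = frozenset().union(*(t.members for t in collection))
                results = ora(
                    query,
                    collection,
                    Background(policy="custom", universe=gmt_universe),
                    alpha=config.alpha,
                )
                lines = ["term\tk\tK\tn\tN\tp_value\tcpv\tsignificant"]
                for r in results:
                    lines.append(
                        f"{r.term}\t{r.input.k}\t{r.input.K}\t{r.input.n}\t{r.input.N}"
                        f"\t{r.p_value:.2E}\t{r.cpv:.2E}\t{int(r.significant)}"
                    )
                path = out / f"ora_module_{label}.tsv"
                path.write_text("\n".join(lines) + "\n", encoding="utf-8")
                written.append(path)

        stage = "summary"
        summary = {
            "nodes": graph.number_of_nodes(),
            "edges": graph.number_of_edges(),
            "modules": len(sizes),
            "modularity": round(partition.modularity, 6),
            "potential_modules": len(potential.labels),
            "universe_size": len(background.universe),
            "K": disease_records[0].input.K if disease_records else 0,
            "background_proportion": round(
                disease_records[0].background_proportion, 6
            ) if disease_records else 0.0,
            "disease_modules": disease_labels,
            "syndrome_modules": syndrome_labels,
            "seed": config.seed,
        }
        path = out / "summary.json"
        path.write_text(json.dumps(summary, sort_keys=True, indent=2) + "\n", encoding="utf-8")
        written.append(path)
        return summary
    except Exception as exc:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
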