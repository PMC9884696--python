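"""End-to-end orchestration: catalogs -> risk genes -> network -> screening -> ORA.

The pipeline is configured with a YAML file whose constants default to the
study conventions: a GeneCards-style relevance cut of 10, an interaction
confidence threshold of 0.9 on the STRING 0–1000 scale, three screening
rounds over all four topological parameters with a strict median boundary,
and a raw-p significance level of 0.05.  Every stage writes its tabular
output and the run ends with a single machine-readable JSON report whose
counts mirror the stage logs.
"""

from __future__ import annotations

import difflib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import enrichment as enr
from . import genesets as gs
from . import network as nw
from . import screening as scr
from . import topology as topo

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ConfigError", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    """The configuration file violated the schema (all errors listed)."""


@dataclass
class CatalogSpec:
    path: str
    source: str
    score_filter: bool = False
    score_column: str = "relevance_score"


@dataclass
class DiseaseSpec:
    name: str
    catalogs: list[CatalogSpec]


@dataclass
class PipelineConfig:
    diseases: list[DiseaseSpec]
    edge_list: str
    score_threshold: float = 10.0
    confidence_threshold: float = 0.9
    score_boundary: str = "ge"
    id_mapping: str | None = None
    keep_isolates: bool = False
    rounds: int = 3
    parameters: list[str] = field(
        default_factory=lambda: list(topo.PARAMETERS)
    )
    median_boundary: str = "gt"
    gmt: dict[str, str] = field(default_factory=dict)
    alpha: float = 0.05
    use_adjusted: bool = False
    min_term_size: int = 3
    max_term_size: int = 2000
    output_dir: str = "out"
    seed: int = 7


_TOP_KEYS = {
    "diseases",
    "score_threshold",
    "network",
    "screening",
    "enrichment",
    "output_dir",
    "seed",
}
_NETWORK_KEYS = {
    "edge_list",
    "confidence_threshold",
    "score_boundary",
    "id_mapping",
    "keep_isolates",
}
_SCREENING_KEYS = {"rounds", "parameters", "median_boundary"}
_ENRICHMENT_KEYS = {
    "gmt",
    "alpha",
    "use_adjusted",
    "min_term_size",
    "max_term_size",
}


def _warn_unknown(keys: set[str], known: set[str], where: str) -> None:
    for key in sorted(keys - known):
        hint = difflib.get_close_matches(key, known, n=1)
        suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
        log.warning("unknown %s key %r%s", where, key, suffix)


def validate_config(path: str | Path) -> PipelineConfig:
    """Load, default-fill and validate a YAML pipeline configuration.

    Schema violations are collected and reported together rather than at
    the first failure; unknown keys produce near-miss warnings.
    """
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    errors: list[str] = []
    _warn_unknown(set(data), _TOP_KEYS, "top-level")

    diseases: list[DiseaseSpec] = []
    raw_diseases = data.get("diseases")
    if not isinstance(raw_diseases, list) or len(raw_diseases) != 2:
        errors.append("'diseases' must list exactly two diseases")
    else:
        for d in raw_diseases:
            cats = [
                CatalogSpec(
                    path=str(c.get("path", "")),
                    source=str(c.get("source", "")),
                    score_filter=bool(c.get("score_filter", False)),
                    score_column=str(
                        c.get("score_column", "relevance_score")
                    ),
                )
                for c in d.get("catalogs", [])
            ]
            if not d.get("name"):
                errors.append("each disease needs a 'name'")
            if not cats:
                errors.append(
                    f"disease {d.get('name', '?')!r} has no catalogs"
                )
            diseases.append(DiseaseSpec(name=str(d.get("name", "?")), catalogs=cats))

    net = data.get("network") or {}
    _warn_unknown(set(net), _NETWORK_KEYS, "network")
    screening = data.get("screening") or {}
    _warn_unknown(set(screening), _SCREENING_KEYS, "screening")
    enrich = data.get("enrichment") or {}
    _warn_unknown(set(enrich), _ENRICHMENT_KEYS, "enrichment")

    cfg = PipelineConfig(
        diseases=diseases,
        edge_list=str(net.get("edge_list", "")),
        score_threshold=float(data.get("score_threshold", 10.0)),
        confidence_threshold=float(net.get("confidence_threshold", 0.9)),
        score_boundary=str(net.get("score_boundary", "ge")),
        id_mapping=net.get("id_mapping"),
        keep_isolates=bool(net.get("keep_isolates", False)),
        rounds=int(screening.get("rounds", 3)),
        parameters=list(
            screening.get("parameters", list(topo.PARAMETERS))
        ),
        median_boundary=str(screening.get("median_boundary", "gt")),
        gmt={str(k): str(v) for k, v in (enrich.get("gmt") or {}).items()},
        alpha=float(enrich.get("alpha", 0.05)),
        use_adjusted=bool(enrich.get("use_adjusted", False)),
        min_term_size=int(enrich.get("min_term_size", 3)),
        max_term_size=int(enrich.get("max_term_size", 2000)),
        output_dir=str(data.get("output_dir", "out")),
        seed=int(data.get("seed", 7)),
    )

    if not cfg.edge_list:
        errors.append("network.edge_list is required")
    if not 0.0 <= cfg.confidence_threshold <= 1.0:
        errors.append("network.confidence_threshold must lie in [0, 1]")
    if cfg.score_boundary not in ("ge", "gt"):
        errors.append("network.score_boundary must be 'ge' or 'gt'")
    if cfg.rounds < 1:
        errors.append("screening.rounds must be >= 1")
    if cfg.median_boundary not in ("gt", "ge"):
        errors.append("screening.median_boundary must be 'gt' or 'ge'")
    bad = set(cfg.parameters) - set(topo.PARAMETERS)
    if bad:
        errors.append(f"unknown screening parameter(s): {sorted(bad)}")
    if not 0.0 < cfg.alpha < 1.0:
        errors.append("enrichment.alpha must lie in (0, 1)")
    if cfg.score_threshold < 0:
        errors.append("score_threshold must be >= 0")
    if errors:
        raise ConfigError(f"{path}: " + "; ".join(errors))
    return cfg


def _assemble_disease(
    cfg: PipelineConfig, spec: DiseaseSpec
) -> gs.DiseaseGeneSet:
    per_source = []
    for cat in spec.catalogs:
        records = gs.read_catalog(
            cat.path,
            cat.source,
            score_column=cat.score_column if cat.score_filter else None,
        )
        if cat.score_filter:
            records = gs.apply_source_filter(records, cfg.score_threshold)
        per_source.append((cat.source, records))
    return gs.union_sources(per_source, spec.name)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage, write all outputs, and return the run report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- gene-set assembly -------------------------------------------------
    set_a = _assemble_disease(config, config.diseases[0])
    set_b = _assemble_disease(config, config.diseases[1])
    risk = gs.intersect_diseases(set_a, set_b)
    gs.write_risk_genes(risk, out / "risk_genes.tsv")
    gs.write_venn_summary(
        risk,
        out / "venn_summary.json",
        source_counts={
            set_a.disease: set_a.source_counts(),
            set_b.disease: set_b.source_counts(),
        },
    )

    # --- network -----------------------------------------------------------
    mapping = (
        nw.read_id_mapping(config.id_mapping) if config.id_mapping else None
    )
    interactions = nw.read_edge_list(config.edge_list, id_mapping=mapping)
    net = nw.build_network(
        interactions,
        risk,
        config.confidence_threshold,
        score_boundary=config.score_boundary,  # type: ignore[arg-type]
        keep_isolates=config.keep_isolates,
    )
    nw.write_graphml(net, out / "network.graphml")
    nw.write_sif(net, out / "network.sif")
    nw.write_edge_table(net, out / "network_edges.tsv")

    # --- topology ----------------------------------------------------------
    table = topo.topology_table(net)
    topo.write_topology_table(table, out / "topology.tsv")

    # --- screening ---------------------------------------------------------
    result = scr.iterate_screening(
        net,
        rounds=config.rounds,
        parameters=config.parameters,
        median_boundary=config.median_boundary,  # type: ignore[arg-type]
    )
    scr.write_rounds_table(result, out / "screening_rounds.tsv")
    core_net = net.subnetwork(result.core_genes)
    core_table = topo.topology_table(core_net) if result.core_genes else []
    topo.write_topology_table(core_table, out / "core_genes.tsv")

    # --- enrichment --------------------------------------------------------
    flagged: dict[str, dict[str, int]] = {}
    missing = {c: p for c, p in config.gmt.items() if not Path(p).exists()}
    gmt_paths = {
        c: p for c, p in config.gmt.items() if c not in missing
    }
    for c, p in sorted(missing.items()):
        log.warning("enrichment: GMT for %s not found at %s; skipped", c, p)
    if gmt_paths:
        terms: list[enr.AnnotationTerm] = []
        for category, p in sorted(gmt_paths.items()):
            terms.extend(enr.read_gmt(p, category))
        for label, query in (
            ("risk", risk.genes),
            ("core", result.core_genes),
        ):
            results = enr.run_ora(
                query,
                terms,
                alpha=config.alpha,
                use_adjusted=config.use_adjusted,
                min_term_size=config.min_term_size,
                max_term_size=config.max_term_size,
            )
            enr.write_enrichment_table(
                results, out / f"enrichment_{label}.tsv"
            )
            flagged[label] = enr.write_enrichment_summary(
                results, out / f"enrichment_{label}_summary.json"
            )
    else:
        log.warning("enrichment: no GMT collections supplied; stage skipped")

    # --- report ------------------------------------------------------------
    report: dict[str, Any] = {
        "diseases": {
            set_a.disease: {
                "genes": len(set_a.genes),
                "per_source": set_a.source_counts(),
            },
            set_b.disease: {
                "genes": len(set_b.genes),
                "per_source": set_b.source_counts(),
            },
        },
        "venn": risk.venn_counts,
        "risk_genes": len(risk.genes),
        "network": {
            "nodes": net.node_count,
            "edges": net.edge_count,
            "dropped_isolated_risk_genes": len(net.dropped_genes),
            "confidence_threshold": config.confidence_threshold,
        },
        "screening": {
            "stop_reason": result.stop_reason,
            "rounds": [
                {
                    "index": r.index,
                    "input_size": r.input_size,
                    "output_size": r.output_size,
                    "medians": {
                        p: round(r.medians[p], 12) for p in topo.PARAMETERS
                    },
                }
                for r in result.rounds
            ],
            "core_genes": sorted(result.core_genes),
        },
        "enrichment": {
            "flagged_terms": flagged,
            "alpha": config.alpha,
            "skipped_categories": sorted(missing),
        },
    }
    (out / "run_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report
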