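"""Seeded synthetic inputs with the structure every pipeline stage assumes.

Real runs of the pipeline start from database extracts (multi-source
disease-gene catalogs, a STRING-style interaction list, GMT annotation
collections) that cannot be redistributed.  This module generates stand-ins
with the same statistical shape and a known ground truth:

* two disease catalogs over a synthetic gene universe with an exactly
  planted cross-disease overlap, observed by several sources with
  independent per-source dropout; one source per disease carries
  GeneCards-style relevance scores of which a configurable fraction falls
  at or below the filter threshold of 10;
* a core–periphery interaction network over genes drawn from the planted
  overlap — a small dense core (elevated on all four topological
  parameters) embedded in a sparse periphery — with retained-edge scores
  at or above the confidence cut and sub-threshold decoy edges, both edge
  orientations written so deduplication is exercised;
* GMT term collections in four categories with a chosen number of terms
  that oversample the planted core, so enrichment recovery is testable.

Every generator is a deterministic function of the spec (including its
seed); regenerating with the same spec yields byte-identical files.
Synthetic gene symbols are "G000001"-style so they cannot collide with
real gene symbols.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from .network import Interaction

log = logging.getLogger(__name__)

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "plant_gene_sets",
    "gen_disease_catalogs",
    "gen_ppi",
    "gen_ppi_interactions",
    "gen_annotations",
    "generate_all",
]

CATEGORIES = ("BP", "CC", "MF", "pathway")

# Independent child-stream tags so each generator's draws are stable
# regardless of which generators are invoked.
_STREAM_SETS = 1
_STREAM_CATALOGS = 2
_STREAM_PPI = 3
_STREAM_ANNOTATIONS = 4


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study.

    Defaults echo the scale of a two-disease comorbidity mining study at
    desk cost: a 3000-gene universe, disease catalogs of 756 and 2096
    genes sharing 459, five catalog sources per disease, and a thresholded
    interaction network of ~407 genes containing a 12-gene dense core.
    """

    seed: int = 7
    n_universe: int = 3000
    disease_sizes: tuple[int, int] = (756, 2096)
    overlap_size: int = 459
    n_sources: int = 5
    source_dropout: float = 0.2
    score_subthreshold_fraction: float = 0.25
    core_size: int = 12
    periphery_size: int = 395
    p_core: float = 0.9
    p_periphery: float = 0.02
    p_core_periphery: float = 0.05
    score_core_range: tuple[int, int] = (900, 1000)
    score_noise_range: tuple[int, int] = (150, 899)
    decoy_edge_fraction: float = 0.25
    n_terms: int = 100
    term_size_range: tuple[int, int] = (10, 500)
    enriched_term_count: int = 5
    enrichment_fold: float = 50.0

    def validate(self) -> None:
        errors: list[str] = []
        if self.overlap_size > min(self.disease_sizes):
            errors.append("overlap_size exceeds a disease size")
        if sum(self.disease_sizes) - self.overlap_size > self.n_universe:
            errors.append("universe too small for the requested disease sets")
        if self.core_size > self.overlap_size:
            errors.append("core_size exceeds overlap_size")
        if self.core_size + self.periphery_size > self.overlap_size:
            errors.append("core + periphery exceed the planted overlap")
        if not 0.0 <= self.source_dropout < 1.0:
            errors.append("source_dropout must lie in [0, 1)")
        if not 0.0 <= self.score_subthreshold_fraction <= 1.0:
            errors.append("score_subthreshold_fraction must lie in [0, 1]")
        for name in ("p_core", "p_periphery", "p_core_periphery"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                errors.append(f"{name} must lie in [0, 1]")
        for name in ("score_core_range", "score_noise_range"):
            lo, hi = getattr(self, name)
            if not 0 <= lo <= hi <= 1000:
                errors.append(f"{name} must be an ordered range in [0, 1000]")
        if self.n_sources < 1:
            errors.append("n_sources must be >= 1")
        if self.enriched_term_count > self.n_terms:
            errors.append("enriched_term_count exceeds n_terms")
        if self.enrichment_fold <= 1.0:
            errors.append("enrichment_fold must be > 1")
        lo, hi = self.term_size_range
        if not 1 <= lo <= hi <= self.n_universe:
            errors.append("term_size_range must fit inside the universe")
        if errors:
            raise ValueError("; ".join(errors))


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    planted_overlap: set[str] = field(default_factory=set)
    planted_core: set[str] = field(default_factory=set)
    planted_enriched_terms: set[str] = field(default_factory=set)
    disease_genes: dict[str, set[str]] = field(default_factory=dict)
    universe: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_overlap": sorted(self.planted_overlap),
            "planted_core": sorted(self.planted_core),
            "planted_enriched_terms": sorted(self.planted_enriched_terms),
            "disease_genes": {
                d: sorted(g) for d, g in sorted(self.disease_genes.items())
            },
            "n_universe": len(self.universe),
        }
        Path(path).write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n"
        )


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def _symbols(n: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, n + 1)]


def plant_gene_sets(spec: SyntheticSpec) -> SyntheticTruth:
    """Draw the universe, the two disease gene sets and their overlap."""
    spec.validate()
    rng = _rng(spec, _STREAM_SETS)
    universe = _symbols(spec.n_universe)
    perm = rng.permutation(spec.n_universe)
    size_a, size_b = spec.disease_sizes
    n_ov = spec.overlap_size
    overlap = [universe[i] for i in perm[:n_ov]]
    only_a = [universe[i] for i in perm[n_ov : size_a]]
    only_b = [universe[i] for i in perm[size_a : size_a + size_b - n_ov]]
    core = sorted(rng.choice(sorted(overlap), size=spec.core_size, replace=False))
    truth = SyntheticTruth(
        planted_overlap=set(overlap),
        planted_core=set(core),
        disease_genes={
            "diseaseA": set(overlap) | set(only_a),
            "diseaseB": set(overlap) | set(only_b),
        },
        universe=universe,
    )
    return truth


def gen_disease_catalogs(
    spec: SyntheticSpec, outdir: str | Path, truth: SyntheticTruth | None = None
) -> tuple[dict[str, list[Path]], SyntheticTruth]:
    """Write per-source catalog TSVs for both diseases.

    Each of the ``n_sources`` sources observes each disease gene
    independently with probability ``1 - source_dropout``; source ``src01``
    additionally carries a relevance score of which
    ``score_subthreshold_fraction`` falls at or below the filter cut 10.
    """
    spec.validate()
    if truth is None:
        truth = plant_gene_sets(spec)
    rng = _rng(spec, _STREAM_CATALOGS)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, list[Path]] = {}
    for disease in sorted(truth.disease_genes):
        genes = sorted(truth.disease_genes[disease])
        files[disease] = []
        for s in range(1, spec.n_sources + 1):
            source = f"src{s:02d}"
            observed = (
                rng.random(len(genes)) >= spec.source_dropout
            )
            rows = [g for g, keep in zip(genes, observed) if keep]
            path = outdir / f"{disease}_{source}.tsv"
            with path.open("w") as fh:
                if s == 1:
                    fh.write("gene_symbol\trelevance_score\n")
                    below = rng.random(len(rows)) < spec.score_subthreshold_fraction
                    low = rng.uniform(0.5, 10.0, len(rows))
                    high = rng.uniform(10.5, 100.0, len(rows))
                    for g, b, lo, hi in zip(rows, below, low, high):
                        fh.write(f"{g}\t{lo if b else hi:.3f}\n")
                else:
                    fh.write("gene_symbol\n")
                    for g in rows:
                        fh.write(f"{g}\n")
            files[disease].append(path)
    log.info(
        "catalogs: %s", {d: len(p) for d, p in files.items()}
    )
    return files, truth


def gen_ppi_interactions(
    spec: SyntheticSpec, truth: SyntheticTruth
) -> tuple[list[Interaction], SyntheticTruth]:
    """Draw the core–periphery interaction list in memory.

    True edges (scored in ``score_core_range``) follow a planted-partition
    model: core pairs with ``p_core``, periphery pairs with
    ``p_periphery``, cross pairs with ``p_core_periphery``.  Decoy edges —
    ``decoy_edge_fraction`` of the true-edge count, scored in
    ``score_noise_range`` — are added on distinct random pairs so that
    confidence thresholding is exercised.
    """
    spec.validate()
    rng = _rng(spec, _STREAM_PPI)
    core = sorted(truth.planted_core)
    rest = sorted(truth.planted_overlap - truth.planted_core)
    periphery = sorted(
        rng.choice(rest, size=spec.periphery_size, replace=False)
    )
    nodes = core + periphery
    is_core = np.array([1] * len(core) + [0] * len(periphery))
    n = len(nodes)
    iu, ju = np.triu_indices(n, k=1)
    kind = is_core[iu] + is_core[ju]  # 2=core pair, 1=cross, 0=periphery
    p = np.where(
        kind == 2,
        spec.p_core,
        np.where(kind == 1, spec.p_core_periphery, spec.p_periphery),
    )
    keep = rng.random(len(iu)) < p
    lo, hi = spec.score_core_range
    true_pairs = list(zip(iu[keep], ju[keep]))
    scores = rng.integers(lo, hi + 1, size=len(true_pairs))
    interactions = [
        Interaction(nodes[int(i)], nodes[int(j)], int(s))
        for (i, j), s in zip(true_pairs, scores)
    ]
    # decoy edges below the confidence cut, on pairs not already drawn
    n_decoys = int(round(spec.decoy_edge_fraction * len(true_pairs)))
    taken = set(true_pairs)
    lo_n, hi_n = spec.score_noise_range
    attempts = 0
    while n_decoys > 0 and attempts < 50 * max(1, n_decoys):
        i, j = sorted(rng.integers(0, n, size=2))
        attempts += 1
        if i == j or (i, j) in taken:
            continue
        taken.add((i, j))
        interactions.append(
            Interaction(nodes[int(i)], nodes[int(j)], int(rng.integers(lo_n, hi_n + 1)))
        )
        n_decoys -= 1
    log.info(
        "ppi: %d nodes, %d true edges, %d decoys",
        n,
        len(true_pairs),
        len(interactions) - len(true_pairs),
    )
    return interactions, truth


def gen_ppi(
    spec: SyntheticSpec, outdir: str | Path, truth: SyntheticTruth | None = None
) -> tuple[Path, SyntheticTruth]:
    """Write the interaction edge list TSV (both edge orientations)."""
    if truth is None:
        truth = plant_gene_sets(spec)
    interactions, truth = gen_ppi_interactions(spec, truth)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "interactions.tsv"
    rng = _rng(spec, _STREAM_PPI + 100)
    rows: list[tuple[str, str, int]] = []
    for it in interactions:
        rows.append((it.gene_a, it.gene_b, it.combined_score))
        rows.append((it.gene_b, it.gene_a, it.combined_score))
    order = rng.permutation(len(rows))
    with path.open("w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for idx in order:
            a, b, s = rows[int(idx)]
            fh.write(f"{a}\t{b}\t{s}\n")
    return path, truth


def gen_annotations(
    spec: SyntheticSpec,
    truth: SyntheticTruth,
    outdir: str | Path | None = None,
) -> tuple[dict[str, list[tuple[str, str, list[str]]]], SyntheticTruth]:
    """Draw GMT term collections, optionally writing one file per category.

    The first ``enriched_term_count`` terms of each category include each
    planted-core gene with probability ``min(1, enrichment_fold * K / N)``
    — an ``enrichment_fold``-times oversampling relative to chance — and
    are filled to size with uniform draws; all other terms are uniform.
    """
    spec.validate()
    rng = _rng(spec, _STREAM_ANNOTATIONS)
    universe = truth.universe or _symbols(spec.n_universe)
    core = sorted(truth.planted_core)
    non_core = sorted(set(universe) - set(core))
    N = len(universe)
    lo, hi = spec.term_size_range
    collections: dict[str, list[tuple[str, str, list[str]]]] = {}
    for category in CATEGORIES:
        terms: list[tuple[str, str, list[str]]] = []
        for t in range(1, spec.n_terms + 1):
            term_id = f"{category}_{t:04d}"
            size = int(rng.integers(lo, hi + 1))
            if t <= spec.enriched_term_count:
                p_inc = min(1.0, spec.enrichment_fold * size / N)
                members = [g for g in core if rng.random() < p_inc]
                n_fill = max(0, size - len(members))
                fill = rng.choice(non_core, size=n_fill, replace=False)
                genes = sorted(set(members) | set(fill.tolist()))
                truth.planted_enriched_terms.add(term_id)
                name = f"synthetic {category} term {t} (planted)"
            else:
                picks = rng.choice(universe, size=size, replace=False)
                genes = sorted(picks.tolist())
                name = f"synthetic {category} term {t}"
            terms.append((term_id, name, genes))
        collections[category] = terms
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for category, terms in collections.items():
            path = outdir / f"{category}.gmt"
            with path.open("w") as fh:
                for term_id, name, genes in terms:
                    fh.write("\t".join([term_id, name, *genes]) + "\n")
    return collections, truth


def generate_all(
    spec: SyntheticSpec, outdir: str | Path
) -> tuple[dict, SyntheticTruth]:
    """Write every pipeline input plus ``truth.json``; return a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = plant_gene_sets(spec)
    catalog_files, truth = gen_disease_catalogs(
        spec, outdir / "catalogs", truth
    )
    edge_path, truth = gen_ppi(spec, outdir / "network", truth)
    _, truth = gen_annotations(spec, truth, outdir / "gmt")
    truth.to_json(outdir / "truth.json")
    manifest = {
        "catalogs": {
            d: [str(p) for p in paths] for d, paths in catalog_files.items()
        },
        "edge_list": str(edge_path),
        "gmt": {c: str(outdir / "gmt" / f"{c}.gmt") for c in CATEGORIES},
        "truth": str(outdir / "truth.json"),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest, truth


def spec_from_mapping(data: dict) -> SyntheticSpec:
    """Build a spec from a plain mapping (YAML/JSON), tolerating lists."""
    kwargs = {}
    for f in SyntheticSpec.__dataclass_fields__:
        if f in data:
            v = data[f]
            kwargs[f] = tuple(v) if isinstance(v, list) else v
    unknown = set(data) - set(SyntheticSpec.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown synthetic-spec key(s): {sorted(unknown)}")
    spec = SyntheticSpec(**kwargs)
    spec.validate()
    return spec
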