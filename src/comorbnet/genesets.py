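"""Assembly of multi-source disease gene catalogs and their intersection.

A disease's gene set is collected from several catalog databases (e.g.
OMIM-, GeneCards-, PharmGkb-, TTD- or DrugBank-style extracts), each
supplied as a TSV file.  Score-bearing catalogs (GeneCards-style relevance
scores) are filtered with a strict lower bound before the per-source lists
are unioned.  Two diseases' unions are then intersected into the risk-gene
set for the comorbidity, with per-gene source provenance retained on both
sides so the Venn-style counts stay auditable.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

__all__ = [
    "GeneRecord",
    "DiseaseGeneSet",
    "RiskGeneSet",
    "normalize_symbol",
    "read_catalog",
    "apply_source_filter",
    "union_sources",
    "intersect_diseases",
    "write_risk_genes",
    "write_venn_summary",
]


class CatalogParseError(ValueError):
    """A catalog file violated the expected TSV layout."""


def normalize_symbol(raw: str) -> str:
    """Uppercase a gene symbol and strip surrounding whitespace.

    Returns the empty string for blank input; callers decide whether blank
    symbols are skipped (file readers) or rejected (record constructors).
    No alias/HGNC resolution is attempted: symbols that differ textually
    across sources stay distinct.
    """
    return raw.strip().upper()


@dataclass(frozen=True)
class GeneRecord:
    """One catalog row: a gene symbol, its source, and an optional score."""

    symbol: str
    source: str
    relevance_score: float | None = None

    def __post_init__(self) -> None:
        if not self.symbol or any(c.isspace() for c in self.symbol):
            raise ValueError(f"invalid gene symbol {self.symbol!r}")
        if self.relevance_score is not None:
            s = float(self.relevance_score)
            if not math.isfinite(s) or s < 0:
                raise ValueError(
                    f"relevance_score must be finite and >= 0, got {s!r}"
                )


@dataclass
class DiseaseGeneSet:
    """A disease's assembled gene set with per-gene source provenance."""

    disease: str
    genes: set[str] = field(default_factory=set)
    provenance: dict[str, set[str]] = field(default_factory=dict)

    def source_counts(self) -> dict[str, int]:
        """Per-source gene counts (the per-ellipse sizes of a Venn plot)."""
        counts: dict[str, int] = {}
        for sources in self.provenance.values():
            for s in sources:
                counts[s] = counts.get(s, 0) + 1
        return dict(sorted(counts.items()))


@dataclass
class RiskGeneSet:
    """Genes shared by two diseases, with provenance from both sides."""

    disease_a: str
    disease_b: str
    genes: set[str]
    per_disease_provenance: dict[str, tuple[frozenset[str], frozenset[str]]]
    venn_counts: dict[str, int]


def read_catalog(
    path: str | Path,
    source: str,
    score_column: str | None = None,
) -> list[GeneRecord]:
    """Read one catalog TSV into :class:`GeneRecord` rows.

    The file must have a header row containing ``gene_symbol``; when
    *score_column* is given that column must exist and hold numbers.
    Rows with a blank symbol are skipped and counted in the log.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "gene_symbol" not in reader.fieldnames:
            raise CatalogParseError(
                f"{path}: missing mandatory column 'gene_symbol'"
            )
        if score_column is not None and score_column not in reader.fieldnames:
            raise CatalogParseError(
                f"{path}: missing score column {score_column!r}"
            )
        records: list[GeneRecord] = []
        n_skipped = 0
        for lineno, row in enumerate(reader, start=2):
            symbol = normalize_symbol(row.get("gene_symbol") or "")
            if not symbol or any(c.isspace() for c in symbol):
                n_skipped += 1
                continue
            score: float | None = None
            if score_column is not None:
                raw = (row.get(score_column) or "").strip()
                if raw:
                    try:
                        score = float(raw)
                    except ValueError:
                        raise CatalogParseError(
                            f"{path}: non-numeric score {raw!r} "
                            f"on line {lineno}"
                        ) from None
            records.append(GeneRecord(symbol, source, score))
    if n_skipped:
        log.info("%s: skipped %d row(s) with blank symbols", path, n_skipped)
    return records


def apply_source_filter(
    records: Sequence[GeneRecord], min_score: float
) -> list[GeneRecord]:
    """Keep records whose relevance score is STRICTLY greater than *min_score*.

    Score-less records pass unchanged: the filter models a GeneCards-style
    relevance cut that only applies to the one source that reports scores.
    """
    if not math.isfinite(min_score):
        raise ValueError("min_score must be finite")
    return [
        r
        for r in records
        if r.relevance_score is None or r.relevance_score > min_score
    ]


def union_sources(
    record_lists: Iterable[tuple[str, Sequence[GeneRecord]]],
    disease: str,
) -> DiseaseGeneSet:
    """Union per-source record lists into one disease gene set."""
    record_lists = list(record_lists)
    if not record_lists:
        raise ValueError("at least one source list is required")
    out = DiseaseGeneSet(disease=disease)
    for source, records in record_lists:
        for rec in records:
            out.genes.add(rec.symbol)
            out.provenance.setdefault(rec.symbol, set()).add(source)
    log.info(
        "%s: %d genes from %d source(s) (%s)",
        disease,
        len(out.genes),
        len(record_lists),
        ", ".join(f"{s}={c}" for s, c in out.source_counts().items()),
    )
    return out


def intersect_diseases(
    set_a: DiseaseGeneSet, set_b: DiseaseGeneSet
) -> RiskGeneSet:
    """Intersect two disease gene sets into the comorbidity risk-gene set."""
    shared = set_a.genes & set_b.genes
    venn = {
        "size_a": len(set_a.genes),
        "size_b": len(set_b.genes),
        "shared": len(shared),
        "only_a": len(set_a.genes - set_b.genes),
        "only_b": len(set_b.genes - set_a.genes),
    }
    if not shared:
        log.warning(
            "no shared genes between %s and %s", set_a.disease, set_b.disease
        )
    provenance = {
        g: (frozenset(set_a.provenance[g]), frozenset(set_b.provenance[g]))
        for g in shared
    }
    log.info(
        "%s ∩ %s: |A|=%d |B|=%d shared=%d",
        set_a.disease,
        set_b.disease,
        venn["size_a"],
        venn["size_b"],
        venn["shared"],
    )
    return RiskGeneSet(
        disease_a=set_a.disease,
        disease_b=set_b.disease,
        genes=shared,
        per_disease_provenance=provenance,
        venn_counts=venn,
    )


def write_risk_genes(risk: RiskGeneSet, path: str | Path) -> None:
    """Write the risk-gene list TSV with per-disease source provenance."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_symbol", "sources_disease_a", "sources_disease_b"])
        for gene in sorted(risk.genes):
            src_a, src_b = risk.per_disease_provenance[gene]
            w.writerow([gene, ",".join(sorted(src_a)), ",".join(sorted(src_b))])


def write_venn_summary(
    risk: RiskGeneSet,
    path: str | Path,
    source_counts: Mapping[str, Mapping[str, int]] | None = None,
) -> None:
    """Write the Venn-count JSON summary (optionally with per-source counts)."""
    payload: dict = {
        "disease_a": risk.disease_a,
        "disease_b": risk.disease_b,
        **risk.venn_counts,
    }
    if source_counts is not None:
        payload["per_source_counts"] = {
            d: dict(sorted(c.items())) for d, c in sorted(source_counts.items())
        }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
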