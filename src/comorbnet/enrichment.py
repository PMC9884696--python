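"""Hypergeometric over-representation analysis (ORA) of gene sets.

A query gene set is tested against GMT term collections (GO BP/CC/MF and
pathway categories).  For each term the overlap ``k`` between the query
(size ``n``) and the term's genes (size ``K``) within a background
universe (size ``N``) is scored with the upper hypergeometric tail
``P(X >= k)``, computed in log space for numerical stability.  P-values
are Benjamini–Hochberg adjusted within each category; the significance
flag follows the raw p-value by default, with an option to flag on the
adjusted value instead.

The background universe defaults to all genes annotated to at least one
term of the category's collection.  Term collections are treated as flat,
pre-propagated sets: no ontology-graph traversal is performed.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

from .genesets import normalize_symbol

log = logging.getLogger(__name__)

__all__ = [
    "AnnotationTerm",
    "EnrichmentResult",
    "read_gmt",
    "hypergeom_tail",
    "bh_adjust",
    "run_ora",
    "write_enrichment_table",
    "write_enrichment_summary",
]

CATEGORIES = ("BP", "CC", "MF", "pathway")


@dataclass(frozen=True)
class AnnotationTerm:
    """One annotation term: an id, a readable name, and its gene set."""

    term_id: str
    name: str
    category: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"term {self.term_id!r} has no genes")


@dataclass
class EnrichmentResult:
    """One term's overlap counts, tail p-value and BH-adjusted p-value."""

    term: AnnotationTerm
    k: int
    K: int
    n: int
    N: int
    p_value: float
    p_adjusted: float
    overlap_genes: frozenset[str]
    significant: bool = False


def read_gmt(path: str | Path, category: str) -> list[AnnotationTerm]:
    """Parse a GMT file (term id, description, tab-separated gene symbols).

    Lines with fewer than three fields, or whose genes all normalize to
    blank, are rejected with their line numbers logged.  Duplicate gene
    symbols within a line are deduplicated; a repeated term id keeps the
    first occurrence.
    """
    path = Path(path)
    terms: list[AnnotationTerm] = []
    seen: set[str] = set()
    n_rejected = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                n_rejected += 1
                log.warning(
                    "%s: line %d: fewer than 3 fields, rejected", path, lineno
                )
                continue
            term_id, name = fields[0].strip(), fields[1].strip()
            genes = frozenset(
                s for s in (normalize_symbol(g) for g in fields[2:]) if s
            )
            if not term_id or not genes:
                n_rejected += 1
                log.warning("%s: line %d: empty term, rejected", path, lineno)
                continue
            if term_id in seen:
                log.warning(
                    "%s: line %d: duplicate term id %r, keeping first",
                    path,
                    lineno,
                    term_id,
                )
                continue
            seen.add(term_id)
            terms.append(AnnotationTerm(term_id, name, category, genes))
    if not terms:
        log.warning("%s: no terms parsed", path)
    return terms


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail ``P(X >= k)`` for X ~ Hypergeometric(N, K, n).

    ``N`` genes in the universe, ``K`` of them in the term, ``n`` drawn as
    the query.  Computed as a log-space sum of hypergeometric point masses
    so small tails stay accurate; returns exactly 1 for ``k == 0``.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K, n <= N; got K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"require 0 <= k <= min(K, n); got k={k}")
    if k == 0:
        return 1.0
    lo, hi = max(k, n - (N - K)), min(K, n)
    if lo > hi:
        return 0.0
    denom = _log_comb(N, n)
    logs = [
        _log_comb(K, i) + _log_comb(N - K, n - i) - denom
        for i in range(lo, hi + 1)
    ]
    # scaled log-sum-exp so tiny tails keep full relative accuracy
    peak = max(logs)
    total = math.fsum(math.exp(v - peak) for v in logs)
    return float(min(1.0, math.exp(peak) * total))


@lru_cache(maxsize=1 << 20)
def _log_comb(a: int, b: int) -> float:
    if b < 0 or b > a:
        return -math.inf  # zero ways
    return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order."""
    m = len(p_values)
    for p in p_values:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p-value {p!r} outside (0, 1]")
    if m == 0:
        return []
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p_values[i] * m / rank)
        adjusted[i] = min(1.0, running_min)
    return adjusted


def run_ora(
    query: Iterable[str],
    terms: Sequence[AnnotationTerm],
    universe: Iterable[str] | None = None,
    alpha: float = 0.05,
    *,
    use_adjusted: bool = False,
    min_term_size: int = 3,
    max_term_size: int = 2000,
) -> list[EnrichmentResult]:
    """Over-representation analysis of *query* against *terms*.

    Terms are grouped by category; within each category the universe is
    either the given *universe* restricted to it or the union of the
    category's term genes, the query is restricted to that universe, each
    term of size within ``[min_term_size, max_term_size]`` (after universe
    restriction) is scored, and BH adjustment is applied per category.
    Results are sorted by category, then ascending p-value, ties broken
    by term id.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    query_set = {normalize_symbol(g) for g in query}
    query_set.discard("")
    fixed_universe = (
        None
        if universe is None
        else {normalize_symbol(g) for g in universe} - {""}
    )
    if fixed_universe is not None and not fixed_universe:
        raise ValueError("universe is empty")

    results: list[EnrichmentResult] = []
    categories = sorted({t.category for t in terms})
    for category in categories:
        cat_terms = [t for t in terms if t.category == category]
        uni = (
            set().union(*(t.genes for t in cat_terms))
            if fixed_universe is None
            else set(fixed_universe)
        )
        q = query_set & uni
        if not q:
            raise ValueError(
                f"query is empty after restriction to the {category} universe"
            )
        N, n = len(uni), len(q)
        cat_results: list[EnrichmentResult] = []
        n_size_filtered = 0
        for term in cat_terms:
            genes = term.genes & uni
            K = len(genes)
            if not min_term_size <= K <= max_term_size:
                n_size_filtered += 1
                continue
            overlap = frozenset(q & genes)
            k = len(overlap)
            p = hypergeom_tail(k, K, n, N) if k else 1.0
            cat_results.append(
                EnrichmentResult(
                    term=term,
                    k=k,
                    K=K,
                    n=n,
                    N=N,
                    p_value=p,
                    p_adjusted=1.0,
                    overlap_genes=overlap,
                )
            )
        if n_size_filtered:
            log.info(
                "%s: %d term(s) outside size range [%d, %d] skipped",
                category,
                n_size_filtered,
                min_term_size,
                max_term_size,
            )
        adjusted = bh_adjust([r.p_value for r in cat_results])
        for r, adj in zip(cat_results, adjusted):
            r.p_adjusted = adj
            crit = r.p_adjusted if use_adjusted else r.p_value
            r.significant = bool(r.k > 0 and crit < alpha)
        cat_results.sort(key=lambda r: (r.p_value, r.term.term_id))
        results.extend(cat_results)
    return results


def write_enrichment_table(
    results: Sequence[EnrichmentResult], path: str | Path
) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "category",
                "term_id",
                "name",
                "k",
                "K",
                "n",
                "N",
                "p_value",
                "p_adjusted",
                "significant",
                "overlap_genes",
            ]
        )
        for r in results:
            w.writerow(
                [
                    r.term.category,
                    r.term.term_id,
                    r.term.name,
                    r.k,
                    r.K,
                    r.n,
                    r.N,
                    f"{r.p_value:.6e}",
                    f"{r.p_adjusted:.6e}",
                    int(r.significant),
                    ",".join(sorted(r.overlap_genes)),
                ]
            )


def write_enrichment_summary(
    results: Sequence[EnrichmentResult], path: str | Path
) -> dict[str, int]:
    """Write (and return) the per-category flagged-term counts."""
    counts: dict[str, int] = {}
    for r in results:
        counts.setdefault(r.term.category, 0)
        if r.significant:
            counts[r.term.category] += 1
    Path(path).write_text(json.dumps(counts, indent=2, sort_keys=True) + "\n")
    return counts
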