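# comorbnet

Comorbidity risk-gene discovery from disease-gene catalogs, protein–protein
interaction (PPI) networks, and annotation term collections.

When two chronic diseases co-occur — the motivating case is diabetic kidney
disease (DKD) complicated by inflammatory bowel disease (IBD) — a standard
way to look for shared genetic mechanisms is: collect each disease's
associated genes from several catalog databases (OMIM-, GeneCards-,
PharmGkb-, TTD-, DrugBank-style extracts), intersect the two catalogs into
a *risk-gene* set, mine the risk genes' PPI network for topologically
central *core* genes, and characterize both sets by Gene Ontology / pathway
over-representation. `comorbnet` implements that whole workflow as a
tested, reusable Python library for bioinformaticians who have the catalog,
edge-list and GMT files in hand (no web access is performed), plus a seeded
synthetic-data generator so every stage can be validated against planted
ground truth.

## The method

1. **Catalog assembly.** Each source is a TSV of gene symbols (uppercased,
   no alias resolution). Score-bearing sources (GeneCards-style relevance
   scores) are filtered to score > 10, strictly. A disease's gene set is
   the union over its sources; the risk-gene set is the intersection
   A ∩ B of the two diseases, with Venn counts |A|, |B|, |A∩B|, |A\B|,
   |B\A| reported.
2. **Network construction.** From a STRING-dialect edge list (combined
   score 0–1000), edges with both endpoints in the risk set and score
   ≥ 0.9 × 1000 are kept (duplicate/reciprocal rows collapse to the
   maximum score; self-loops are rejected). Risk genes left without an
   edge are dropped and reported.
3. **Topology.** For each node: degree *k*; betweenness centrality
   $C_B(v) = \frac{2}{(n-1)(n-2)} \sum_{s \ne v \ne t} \sigma_{st}(v)/\sigma_{st}$
   (exact shortest-path counting); component-local closeness
   $C_C(v) = (c-1)/\sum_{u} d(v,u)$; clustering coefficient
   $C(v) = e_v / \binom{k}{2}$ (0 for *k* < 2). All fractional values lie
   in [0, 1], following Cytoscape NetworkAnalyzer conventions.
4. **Median screening.** Each round keeps nodes **strictly above the
   median** on all four parameters, induces the subnetwork on the kept
   nodes, recomputes everything there, and repeats (default three rounds).
   A round that keeps nothing stops the iteration and reports the previous
   round's set as the core.
5. **Enrichment.** For each GMT term, the overlap *k* between the query
   (size *n*) and the term (size *K*) in the universe (size *N*) is scored
   with the exact hypergeometric upper tail
   $p = \sum_{i \ge k} \binom{K}{i}\binom{N-K}{n-i} / \binom{N}{n}$,
   BH-adjusted within each category (BP/CC/MF/pathway); terms with raw
   p < 0.05 are flagged.

## Worked example

`examples/03_topology_and_screening.py` builds a synthetic network with a
planted 12-gene dense core in a 200-gene sparse periphery and screens it:

```
round 1: 212 -> 39 nodes (median degree 5)
round 2: 39 -> 12 nodes (median degree 4)
round 3: 12 -> 0 nodes (median degree 10)
stop reason : empty-selection
core genes  : 12; planted-core recall 1.00
```

Rounds 1–2 strip the periphery (few periphery nodes beat the medians on
all four parameters at once); round 3 keeps nothing because the surviving
near-clique is too symmetric for a strict median cut, so the 12-gene
round-2 selection is reported — here exactly the planted core.
`examples/04_enrichment.py` then tests such a core against synthetic GMT
collections; the five planted BP terms rank first with p-values around
1e-19 to 1e-12, and all planted terms across the four categories are
recovered at raw p < 0.05. The other examples cover catalog intersection,
network thresholding, and the full pipeline (`run_report.json`).

A thin CLI mirrors the stages:

```sh
comorbnet simulate --outdir fixtures/
comorbnet run --config config.yaml
comorbnet screen --edges interactions.tsv --rounds 3 --out rounds.tsv
```

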