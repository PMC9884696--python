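# Methods

## Scope and model

`comorbnet` formalizes a catalog-mining workflow for two comorbid
diseases: multi-source gene-set assembly, set intersection, thresholded
PPI-network construction, iterated median screening of four node-topology
parameters, and hypergeometric over-representation analysis (ORA). The
package consumes files (catalog TSVs, a STRING-dialect edge list, GMT
collections); it never queries databases, resolves gene aliases, or
traverses the GO graph. Symbols are compared textually after uppercasing,
so the same gene listed under different aliases in different sources stays
distinct — an accepted limitation of symbol-level mining.

## Stage conventions

**Catalog filter.** Relevance scores are filtered with a strict bound
(score > 10 by default): a record at exactly the threshold is excluded.
Sources without a score column are never filtered. Both choices mirror
how GeneCards-style relevance cuts are used in practice, where only one
catalog in the mix carries scores.

**Confidence threshold.** The STRING combined score is an integer in
[0, 1000]; confidence 0.9 maps to score ≥ 900 (the "highest confidence"
convention). The boundary is configurable to strict (`gt`) for
sensitivity analysis. Duplicate and reciprocal rows collapse to one
undirected edge keeping the maximum score, because STRING exports list
both orientations. Risk genes with no surviving edge are dropped from the
network by default (they cannot carry topological signal) and reported so
the reduction from risk genes to network nodes stays auditable;
`keep_isolates` retains them for diagnostics.

**Topology.** The four parameters follow Cytoscape NetworkAnalyzer
conventions so every value is comparable on a fixed scale:

- betweenness is normalized by (n−1)(n−2)/2 with n the whole-network node
  count (not the component size); on networks dominated by one large
  component — the intended regime — the distinction is immaterial, and
  the whole-network convention matches the reference tool. Shortest-path
  counting is exact (Brandes), never sampled.
- closeness is component-local: (c−1)/Σd over the node's component of
  size c, without the Wasserman–Faust cross-component scaling, so
  disconnected graphs still yield values in [0, 1]. A node alone in its
  component scores 0.
- clustering is defined as 0 for degree < 2 rather than undefined, so
  every node carries four comparable values into the median step.

Computation is delegated to networkx; the test suite checks all three
fractional parameters against independent brute-force all-pairs-geodesic
and triangle-count oracles (1e−9 on 100 random graphs) and against closed
forms on paths, stars, cycles and cliques (1e−12).

**Median screening.** "Above the median" is read strictly: a node must
exceed the median on *every* screened parameter; values equal to the
median are excluded. Medians use the mean-of-middles convention for even
counts. Strictness has two structural consequences, both deliberate and
tested. First, with tie-free values a round keeps at most ⌊n/2⌋ nodes, so
each effective round at least halves the network. Second, symmetric
graphs select nothing: every node of a vertex-transitive graph sits
exactly at each median. Ties can also defeat single nodes on small
graphs — on the 5-node triangle-plus-pendant graph (edges A–B, A–C, A–D,
B–C, D–E) the hub A ties the clustering median at 1/3 and the strict
four-parameter rule keeps nothing, while the three-parameter variant
{degree, betweenness, closeness} keeps exactly {A}. Both the parameter
list and the boundary (`ge`) are configurable; the default is all four
parameters with the strict boundary. When a round keeps nothing the
iterator stops and reports the previous round's selection: the procedure
is a ranking device, and discarding everything would be uninformative.
The default of three rounds with early stopping matches how the screen is
used to reduce a few-hundred-node network to a handful of core genes.

**Enrichment.** The hypergeometric upper tail is computed in log space
(cached log-binomials, scaled log-sum-exp) and is exact to ~1e−13
against rational enumeration for all parameter combinations with N ≤ 60.
k = 0 returns exactly 1. BH adjustment implements the step-up formula
directly and is cross-checked against statsmodels. The background
universe defaults to the union of the category's term genes — the common
package default when no custom background is supplied — and each category
is adjusted separately. The significance flag uses raw p < 0.05 by
default (mirroring how catalog-mining studies report term counts), with
`use_adjusted` to flag on the BH value instead; both are always reported.
Terms outside the size range [3, 2000] (after universe restriction) are
skipped, preventing degenerate single-gene terms.

## Synthetic data

The generator produces the three input kinds with planted ground truth:

- **Catalogs**: a universe of synthetic symbols ("G000001"… — collision-
  free with real gene symbols), two disease sets with an exactly planted
  overlap, each gene observed by each of five sources independently with
  probability 1 − dropout (default dropout 0.2, a realistic level of
  catalog incompleteness; with dropout 0 the pipeline recovers the
  planted overlap exactly). One source per disease carries relevance
  scores with a configurable sub-threshold fraction (default 0.25) so the
  >10 filter is exercised.
- **Network**: a planted-partition core–periphery graph (core pairs wired
  with p_core = 0.9, periphery 0.02, cross 0.05) whose true edges score
  ≥ 900 and whose decoy edges (25% of the true count) score below 900;
  both edge orientations are written so deduplication is exercised.
- **Annotations**: four GMT categories of 100 terms each with sizes
  uniform on [10, 500] (the conventional ORA size window); five terms per
  category include each planted-core gene with probability
  min(1, 50·K/N) — a 50-fold oversampling relative to chance.

Defaults echo the scale of a two-disease catalog-mining study at desk
cost: universe 3000, disease sizes 756 and 2096, overlap 459, periphery
395, which yields a thresholded network of ~407 nodes and ~1800 edges
containing a 12-gene core. All generators are deterministic functions of
the spec (seed included); regeneration is byte-identical.

What the generator does **not** emulate: realistic degree distributions
(STRING subnetworks are heavy-tailed, the synthetic periphery is
Erdős–Rényi), alias ambiguity, correlated source coverage, and GO term
overlap structure. Passing recovery tests therefore show the pipeline's
operations are correct on data with the assumed structure, not that the
biological conclusions of any particular study are right.

## Test and validation sizes

Property and recovery tests use sizes chosen to make the statistics
informative at interactive cost: centrality oracles on 100 random graphs
of up to 30 nodes; hypergeometric exactness over every parameter
combination with N ≤ 60; planted-core recovery averaged over 20 seeded
networks (12-gene core, 200-gene periphery), where mean recall ≥ 0.8 —
individual seeds vary because a strict median cut inside an asymmetric
near-clique occasionally keeps a small subset rather than stopping empty;
ORA null calibration over 200 unplanted collections, where the raw-p
false-flag rate sits slightly below the nominal 0.05 (≈0.04) owing to the
discreteness of the hypergeometric tail. With the larger default
periphery (395 nodes) the same occasional third-round over-screening
lowers mean core recall below the 200-periphery setting — visible in the
per-round logs — which is why recovery claims are stated at the
200-periphery configuration.

## Known limitations

- Symbol-level matching; no HGNC/alias resolution.
- GMTs are treated as flat, pre-propagated sets; no ontology traversal or
  term-redundancy reduction.
- The screening rule is the all-parameters-above-median heuristic only;
  alternative hub detectors (MCC, MCODE, k-core) are out of scope.
- Unweighted shortest paths throughout; confidence scores are used only
  for thresholding, never as distances.
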