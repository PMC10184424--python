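# Methods

This note records the modelling choices behind `kfcnet`, the parameters that
matter, what the synthetic data does and does not emulate, and the numerical
conventions.

## The pipeline and its assumptions

The package treats a multi-herb formula as a four-layer undirected graph:
chemical components, their predicted protein targets, a protein–protein
interaction (PPI) layer, and disease (pathogenic) genes weighted by
literature support. The working assumptions are:

* **Simple, unweighted edges.** Duplicate component–target predictions
  collapse to one edge; PPI confidence scores are preserved on file
  round-trips but never used in computation (no score threshold is applied
  to user-supplied PPI exports — filtering is the supplier's choice).
* **Exact symbol matching** after a single upper-casing normalization at
  ingest. No alias resolution: resolving gene synonyms would silently import
  an external database dependency, and mismatches are better surfaced than
  guessed. Proteins appearing only in the PPI list are kept with a `linker`
  layer label.
* **Evidence-derived node weights.** A disease gene with `n` supporting
  publications gets weight `1 + ln(1 + n)`. Publication counts are extremely
  right-skewed (most genes have a single supporting reference, a few have
  dozens), so the logarithm keeps a famous gene from dominating every
  influence sum while preserving the ordering.
* **Isolated weighted genes are kept.** A disease gene with no edge cannot
  propagate influence, but dropping it would shift the median used for
  key-network extraction; it stays, scored 0.

## Node importance

`score(v) = p(v) · I(v)` with `p(v) = deg(v)/(N−1)` (connection
probability) and `I(v) = Σ w(u)·α^d(v,u)` over nodes within `max_depth`
hops. Tunables:

* `alpha = 0.5` — per-hop damping, dimensionless, in (0,1). Direct
  neighbours count half their weight, two-hop neighbours a quarter, and so
  on; values near 1 flatten the score toward "total reachable weight",
  values near 0 reduce it to a weighted degree.
* `max_depth = 3` — propagation horizon in hops. Three hops spans
  component → target → interacting protein → disease gene, the longest
  causal chain the layer structure encodes, and bounds the all-pairs cost on
  large networks.

The scorer sits behind the same dispatch as six classical centralities
(degree, closeness, radiality, clustering coefficient, neighborhood
connectivity, average shortest path length), so alternative formulations
drop in without touching downstream stages. Distance-based centralities are
computed per connected component with `n` the component size; an isolated
node gets closeness/radiality 0 and average shortest path `inf` (infinitely
peripheral — never "key").

**Key-network extraction** keeps nodes *strictly above* the median score of
all nodes pooled across layers (a per-layer median would let a weak layer
promote its own mediocre nodes). Average shortest path length is negated
before thresholding so "above median" always means "more central". If all
scores tie, the key set is empty and a warning is raised rather than
guessing.

## CDR and KFC selection

The Contribution Decision Rate model is greedy weighted maximum coverage:
the value of a component is the number of *not-yet-covered* elements of the
coverage universe adjacent to it in the key network. Choices made here:

* **Universe = covered nodes** (default `adjacent`): the non-component key
  nodes adjacent to at least one component, so selecting every component
  always reaches coverage 1. Alternatives: `all` (every non-component key
  node; nodes no component touches stay uncovered and a requested threshold
  may be unreachable — a warning path) and `edges` (edge coverage).
* **Greedy, not exact knapsack.** Maximum coverage is NP-hard; the greedy
  order carries the classical `1 − 1/e` guarantee, which the test suite
  verifies against exhaustive search on instances up to 12 components, with
  exact agreement when component target sets are disjoint.
* **Deterministic tie-breaks** — higher key-network degree, then
  lexicographic id — so rankings are bit-for-bit reproducible. Components
  with zero marginal gain are appended in tie-break order with CDR 0.
* **KFC threshold 0.90**: the shortest ranking prefix with cumulative
  coverage ≥ 90 %. A static mode (rank once by individual coverage, no
  marginal re-evaluation) is available for comparison.

## Enrichment and method comparison

ORA uses the upper-tail hypergeometric probability `P(X ≥ k)` for a query of
`n` genes against a term with `K` annotated genes in a background of `N`,
with Benjamini–Hochberg adjustment across tested terms. Defaults:

* background = union of all GMT genes (overridable); query genes outside it
  are dropped with a logged count;
* significance on **raw p < 0.05**, because that is the conventional cutoff
  for this analysis; an adjusted-p mode is provided since ORA tools differ
  here, and the ambiguity is surfaced rather than hidden.

*Effective terms* are the significant terms shared by the full target gene
set and the disease gene set; a method's coverage is the fraction of
effective terms its key-network genes recover. The comparison is
annotation-agnostic: GO and pathway collections are just two GMT inputs.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical shape of a formula-scale dataset
(defaults: 7 herbs, 523 components of which ~54 % pass the screen, 1221
targets at mean component degree 40, 2973 disease genes):

* component CT degrees: lognormal (σ = 0.9), rescaled to the configured
  mean; targets attached preferentially, each target guaranteed one edge;
* publication counts: zeta/Zipf with exponent 2 by default — >50 % of genes
  at one publication and ~1 % above 40, matching both tail features of real
  disease-gene evidence; a geometric option exists but cannot produce the
  heavy upper tail;
* PPI: Barabási–Albert (m = 3 at full scale), then degree-preserving
  double-edge swaps that make the disease-gene layer assortative
  (`ppi_homophily = 0.9`), an intra-top-decile module
  (`disease_module_degree = 6`), top-decile genes biased toward
  well-connected positions (`hub_weight_bias = 1.0`) and disease-only genes
  toward the periphery (`fresh_gene_bias = −3`). These mirror the empirical
  facts that disease genes cluster in interaction networks and that heavily
  studied genes are better connected;
* planting: the ground-truth key components are drawn from the 55th–90th
  percentile of the degree distribution; at `planting_strength = 3` each
  redirects 90 % of its links (plus 30 % extra) into a round-robin exclusive
  slice of the top weight decile and of that decile's PPI neighbourhood.
  Redirection rather than pure addition keeps their raw degree ordinary, so
  the planted signal lives in *where* the links go, not in how many there
  are;
* GMT: signal terms drawn from both sides of the planted neighbourhood
  (so they enrich in both the target and the disease query), decoy terms
  uniform, plus 15 000 background-only genes so queries are small relative
  to the ORA background, as with genome-scale annotation.

These structural defaults were fixed once, during generator design, by
checking that the planted structure is actually present and weight-led
(recoverable by the weight-aware score, not trivially by degree) — not by
reference to any downstream test threshold.

Not emulated: real chemical structures or correlated ADMET descriptors,
gene-identifier aliasing, GO DAG topology or term redundancy, PPI confidence
scores, and any correlation between a component's concentration and its
connectivity. Passing tests therefore demonstrate that the pipeline's
inferences are correct *given* the stated statistical structure, not that
the structure matches any particular organism or database snapshot.

## Problem sizes used in the tests

Statistical properties (importance-vs-baseline coverage ordering, planted
recovery, rank comparisons) run on 20 replicates at a scaled-down condition
— 80 components, 150 targets, 600 disease genes, mean component degree 5,
PPI attachment 2, 12 planted components, 2000 background genes — chosen so a
replicate still has distinct layers and a meaningful decile while the whole
suite stays interactive. Exactness checks (oracle equivalence, greedy
bounds, hypergeometric enumeration) use graphs up to 60 nodes and instances
up to 12 components, where brute force is affordable. The acceptance script
additionally runs one formula-scale pipeline (523/1221/2973).

## Numerical conventions and degenerate inputs

* Medians via `numpy.median` over finite values; `inf` scores (isolated
  nodes under average shortest path) are excluded from the median but can
  never be selected.
* Coverage fractions are computed as `covered_count / universe_size` at each
  step, not as running float sums, so cumulative values are exact and the
  marginals sum to the final cumulative.
* Empty networks, empty layers, empty key sets, unreachable coverage
  thresholds and empty ORA queries all raise or warn explicitly; nothing is
  silently coerced to zero.
* Missing ADMET values are `None` end to end; a missing value excludes the
  rule from the conjunction (otherwise every compound from a source without
  OB predictions would be discarded wholesale, which would contradict the
  screen's purpose of enriching, not truncating, the candidate set).

## Known limitations

* The importance model is one concrete operationalization of
  "influence and control plus connection probability"; other readings
  (e.g. eigenvector-style propagation) would slot behind the same interface
  but are not implemented.
* The CDR universe counts nodes, not biological effect sizes; components
  covering many weakly relevant nodes can outrank components covering few
  critical ones.
* Whether the three ADMET criteria combine conjunctively is configurable
  (`all-rules` default) because screening conventions differ between
  sources; results at non-default settings are not characterized by the
  test suite.
* Symbol matching is exact; datasets mixing HGNC symbols with aliases will
  silently under-merge.
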