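# Methods

## Scope and model

The package implements the desk half of a classic aging-transcriptome
study design: start from a gene × sample read-count matrix with group
labels (young vs one or more aged groups), normalize to RPKM, call DEGs
per contrast with a fold-change + t-test rule, intersect the calls across
contrasts, carry the interesting set into a merged protein/gene
interaction network, and characterize the seeded neighborhood (hubs,
singletons, functional enrichment). Upstream read processing (trimming,
alignment, counting) is out of scope — the pipeline starts at the count
matrix — as is any network rendering; networks are exported as SIF and
GraphML for external viewers.

## Differential expression

RPKM uses the column sum of the count matrix as the library size, since
true mapped-read totals are not available once the analysis starts from a
count matrix. The DEG rule is the conjunction of two thresholds:

* fold change on group means with a pseudocount,
  `(x̄_alt + c)/(x̄_ref + c)` with `c = 1 RPKM` by default, which keeps
  zero-mean genes finite; ratio-of-means, not mean-of-ratios.
* a two-sided two-sample t-test at `p ≤ p_max`, Welch variant by default
  (no equal-variance assumption; group sizes of 8/6/3 make pooling
  fragile), computed on `log2(RPKM + 1)` by default to stabilize
  variance. Student's pooled test and a raw-RPKM scale are available by
  flag because published threshold pipelines are often ambiguous about
  both choices; the choice is reported in the thresholds object.

No multiple-testing correction is applied by default — the rule is a raw
`p ≤ 0.05` filter as commonly practiced with this design — but
Benjamini–Hochberg adjustment is available (`bh_adjust`) and is always
reported in enrichment output.

Degenerate inputs: genes that are all-zero in both groups, and
zero-variance genes with equal means, are UNTESTABLE (no p-value). A
zero-variance gene whose means differ is assigned p = 0 (infinite
separation). Groups with fewer than two samples are an error, not a
warning: a t-test is undefined there.

## Set algebra

`venn_partition` decomposes 2–3 labeled sets into all 3 (or 7) disjoint
regions by exact membership pattern; the classic "overlap" count of a
Venn diagram is the union of regions containing both labels
(`intersection()`), not the exclusive region. `compare_experiments`
reports overlap size, Jaccard index, and — when a universe is supplied —
the hypergeometric upper-tail probability of an overlap at least as
large.

## Interactome

Both supported edge-list dialects reduce records to gene-symbol pairs
with taxids. Matching is case-insensitive (symbols are uppercased
internally, display case preserved), because mouse (`Ywhae`) and human
(`YWHAE`) casing conventions differ while within-species joins must be
robust to curation noise. Only within-species records pass the species
filter; cross-species and off-target taxa counts are reported. The merge
produces a simple graph: duplicate unordered pairs collapse (sources
unioned), self-loops are dropped and counted (hub analysis concerns
distinct partners; a retain flag exists). Edges are unweighted; evidence
strings are carried opaquely and an optional record-level predicate
supports evidence filtering. The MITAB parser takes the first alias
tagged `(gene name)`, then `(display_short)`, else skips the row and
counts it; lenient skipping (with counters) is the default because public
MITAB files routinely contain non-gene interactors.

## Subnetworks and hubs

Two seeding modes: `SEEDS_ARE_DEGS` admits every direct partner of the
seed list; `NEIGHBORS_MUST_BE_DEGS` admits only partners inside a
supplied DEG universe (for seeding with an annotation set). Depth-1
subnetworks keep only seed-incident edges by default — a star expansion,
which matches how first-neighbor networks are typically displayed, where
the edge count stays below what an induced subgraph would give — with an
induced-mode flag. Depth-2 subnetworks default to induced edges, since a
two-step closure is normally reported with all internal interactions.
Seeds with no admitted partner (including seeds absent from the
interactome) are singletons, reported rather than raised: missing
database coverage is an expected outcome. Hub ranking is by
within-subnetwork degree with deterministic alphabetical tie-breaks.

## Enrichment

The over-representation p-value is the hypergeometric upper tail
`P(X ≥ k)`, identical to a one-sided Fisher exact test (property-tested
against `scipy.stats.fisher_exact` on random small instances). The EASE
variant computes the tail at `k − 1` (floored at 0), which penalizes
single-gene overlaps; it is provided because the popular DAVID service
reports EASE scores by default. The background defaults to the detected
gene universe of the expression matrix, not a whole genome — standard
practice, and configurable. Term clustering / kappa grouping is not
implemented; each term is tested alone.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not raw sequencing:

* counts: integer gene baselines drawn uniformly on
  `baseline_mean_range` (default 20–500), multiplied by a mean-one
  log-normal factor with coefficient of variation `noise_cv`
  (default 0.2), rounded to integers. Log-normal multiplicative noise is
  the simplest model consistent with a fold-change-on-means analysis; a
  negative-binomial count layer is deliberately left out.
* effects: a `de_fraction` (default 5%) of genes is planted, half up
  (mean × `effect_fc`) and half down (mean ÷ `effect_fc`,
  default fold 4) in every aged group. With `noise_cv = 0` the realized
  count-mean ratio equals the planted fold exactly whenever the scaled
  means are integral (rounding is the only nonlinearity); the invariant
  test uses such a configuration. Group sizes default to 8/6/3.
* gene lengths: uniform on 500–5000 bp so the RPKM length denominator is
  actually exercised.
* interactome: an Erdős–Rényi background over the gene universe plus a
  planted hub wired to exactly `hub_target_count` partners, drawn
  preferentially from the annotated up-regulated planted genes; a
  configurable fraction of edges appears in both emitted database files
  (BioGRID-TAB and MITAB dialects), the rest split between them, so the
  merge step has real work to do. A few annotated up-genes are excluded
  from the interactome entirely as planted singletons, and optional
  cross-species rows exercise the species filter.
* annotations: an "immune_response"-like term covering the planted
  up-genes plus a few null genes, and a "hippocampal_development"-like
  term mixing down-, up- and null genes.

What passing on these fixtures does **not** show: robustness to
count-model misspecification (overdispersion beyond log-normal),
batch/library-composition effects, annotation incompleteness, or the
biases of real curated interactomes (degree assortativity, study bias).
The simulator's graph is unrealistic in degree distribution by design —
it exists to make planted structure exactly recoverable.

## Problem sizes and determinism

Default validation runs use 1000 genes × 17 samples and interactomes of a
few hundred nodes; oracle-equivalence suites use ≥ 200 random instances
of ≤ 50 nodes (graphs) or N ≤ 60 (hypergeometric tables), sizes at which
brute-force references are exact and instant. All randomness flows
through explicit integer seeds (`numpy.random.default_rng`); no stage
seeds from the clock. Run manifests contain no timestamps or absolute
paths, so a rerun with identical config and inputs is byte-identical —
this is asserted, not assumed.

## Known limitations

* Published headline counts from real datasets (specific DEG totals,
  network node/edge counts) are not reproduced here: they depend on
  archival database snapshots and deposited raw data, and the package
  validates the operations on ground-truthed fixtures instead.
* Symbol-level merging cannot distinguish isoforms or map orthologs;
  human and mouse networks are built separately and compared only at the
  set level.
* The fold-change rule tests ratio-of-means only; shrinkage estimators
  and dispersion-modelling DE methods are intentionally out of scope.
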