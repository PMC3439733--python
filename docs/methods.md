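# Methods

## Scope

`gsatk` is a desk-scale re-implementation of the analytical layer of an
integrated gene-set database: similarity scoring between gene sets,
over-representation search of query gene lists, differential gene-set
expression from per-gene fold changes, gene-set association network (GSAN)
construction and export, and scale-distribution statistics. It operates on
user-supplied collections (GMT or a long membership table) or on synthetic
collections from its own generator; it does not ship, fetch, or parse the
native dumps of any curated database.

## Gene-set similarity

For gene sets P_i, P_j the score blends the Jaccard coefficient S_L =
|P_i∩P_j| / |P_i∪P_j| with the cover coefficient S_R = |P_i∩P_j| /
min(|P_i|, |P_j|):

    S_ij = α·S_L + (1−α)·S_R,   α ∈ [0, 1], default α = 0.8

The cover term keeps the score high when a large set contains a small one,
a situation plain Jaccard penalizes heavily. Because min(|P_i|,|P_j|) ≤
|P_i∪P_j|, S_L ≤ S_R always, so the blended score is non-increasing in α:
small α inflates scores (cover-dominated, right-shifted distribution),
large α deflates them. The α-scan utility (`alpha_sensitivity`) reports
per-α histograms, means and sample skewness of all pairwise scores
descriptively; no distributional test is applied, since the shape question
("roughly Poisson-like in the mid-α band") is a visual diagnostic, not an
inferential one.

All-pairs computation uses an inverted gene→set index, so memory is
proportional to the number of overlapping pairs rather than to n². Pairs
with zero overlap are never emitted: an association requires shared genes.

## Over-representation search

A query of q genes is tested against each candidate set of scale K under
the hypergeometric null: the one-sided p-value is P(X ≥ hits) for X ~
Hypergeom(N, K, q), the upper tail of Fisher's exact test on the 2×2
membership table (computed via `scipy.stats.hypergeom.sf`). Defaults follow
common practice for disease gene-set search: a hit floor of 2, p < 0.05,
and results ranked by decreasing hits, then increasing p, then set id.

Decisions that were genuinely open:

* **Universe.** The background size N materially changes p-values and is
  rarely stated in applications. Default `"auto"` = size of the union of
  the universes of all loaded collections; any integer override is
  accepted, and the run manifest records the value actually used.
* **FDR family.** Benjamini–Hochberg (`statsmodels`) over the
  post-exclusion sets that pass the hit floor; the p threshold is applied
  after adjustment. Applying the floor first keeps the family to the tests
  actually of interest; both orderings are defensible, only one is
  implemented, and it is stated here.
* **Disease-profile search** builds the query as the union of the genes of
  every name-matching set in the designated disease sources, then excludes
  those sources from the results: they defined the query, so testing them
  would be circular.

Hit-count ranking has a structural consequence worth knowing: a set much
larger than the true target can legitimately accumulate more raw hits
(background hits plus genes shared with the target) than the target itself.
Planted-signal recovery is therefore assessed on collections whose scales
are pathway-like relative to the universe (10–100 genes at a universe of
1,000); with dominant very large sets the top-by-hits slot belongs to them
by construction, and ranking by p-value instead would change the behavior —
but decreasing-hits order is the convention this toolkit follows.

## Differential gene-set expression

Per-gene fold changes are consumed as produced by an upstream differential
analysis (one row per gene; several probes per gene are collapsed by
keeping the row with maximal |FC|). ABS_FC = |FC|. A gene set's statistic
is the modified p-norm (a power mean) over its *available* genes — those
present in the expression table:

    NORM_ABS_FC = ( (1/n) Σ x_i^p )^(1/p),   x_i = ABS_FC_i,  default p = 6

The 1/n normalization makes the statistic a generalized mean: bounded by
min and max of x, equal to the arithmetic mean at p = 1, non-decreasing in
p, and → max(x) as p → ∞. p = 6 accentuates the most differential genes
without collapsing onto the single maximum. Numerical note: the maximum is
factored out before exponentiation, so |FC| of any magnitude survives
p = 6 without overflow. Sets with no measured genes get an undefined score
(not 0) and sort last in prioritization — a zero would silently outrank
nothing. Fold changes are not log-transformed by default; a `log2` flag
converts log2 ratios to linear fold changes on ingestion for tables that
ship log-scale values.

Because the statistic is gene-level, any set containing strongly
differential genes scores high — including small sets that share a few hot
genes with the truly perturbed set (a small set holding one hot gene x
scores ≈ x·n^(−1/6) at p = 6). This is the intended behavior of the
statistic, and it bounds how cleanly a planted target can be recovered when
set memberships overlap heavily; the recovery simulations below use a
transcriptome-scale universe (5,000 genes) with curated-pathway set sizes
(20–50) so that leakage of boosted genes across sets is low.

## GSAN construction

Candidate edges are all pairs with overlap ≥ 1. Each is scored by the
similarity above and, when the Fisher filter is on, tested for
over-representation of the shared genes — the smaller set is treated as the
"query" drawn against the larger under the configured universe (the 2×2
orientation is a convention; it is recorded in the graph's parameters).
BH-FDR is computed over all candidates; retained edges satisfy score ≥ 0.1,
p < 0.05 and FDR < 0.05 by default. All input sets remain as nodes;
isolates are kept and flagged, since a filtered network that silently drops
nodes misrepresents the input. Node attributes carry scale (rendered as
node size), NORM_ABS_FC (node color) and source (node line color); edge
attributes carry the score (edge width) and the test results. Exports
(node/edge TSV at full double precision, SIF with bare lines for isolates,
GraphML via networkx) are deterministic and byte-stable; node/edge tables
round-trip to an identical graph.

## Scale distribution

The scale of a set is its member count. The distribution module tabulates
the exact frequency of each distinct scale (no binning — one point per
scale) and fits OLS to (log10 scale, log10 frequency) via
`scipy.stats.linregress`, reporting slope, intercept and R². A
zero-variance response returns an explicit degenerate marker rather than a
fabricated R² of 0 or 1. All points enter the fit; no truncation of extreme
scales is applied. This is a descriptive power-law diagnostic, not a formal
power-law test (no maximum-likelihood exponent estimation or
goodness-of-fit machinery).

## Synthetic data

The generator stands in for database snapshots and microarray-derived fold
changes that cannot be redistributed. What it emulates, and what it does
not:

* **Scales** follow a truncated discrete power law (default exponent 2),
  matching the many-small/few-large regime of integrated collections.
* **Membership** models: `independent` (uniform sampling — overlap purely
  by chance, E[|A∩B|] = |A||B|/N), `nested-chain` (each set a superset of
  the previous — maximal cover-coefficient structure), `block-community`
  (sets in a block share a planted core — community structure as produced
  by related pathways).
* **Expression**: background |FC| is log-normal with median 1.2 and σ ≈
  0.31 (so ~5% of genes exceed |FC| 2 — a typical microarray fold-change
  marginal), signs random, p-values uniform. Target-set genes get |FC|
  multiplied by the effect size (default 3) and p-values uniform below
  0.05. This is a stand-in distributional choice, not a claim about any
  particular dataset.
* **Not emulated**: probe-level intensities, normalization artifacts,
  correlated expression between co-regulated genes, curation biases, and
  real gene nomenclature (symbols are `G000001`…). Passing recovery tests
  on this generator therefore demonstrates correctness of the pipeline
  and sensible behavior under controlled overlap/signal structure — not
  performance on any real database.

Determinism: all randomness flows from the spec's single integer seed
through named sub-streams (`numpy` `default_rng` with seed sequences), and
every sampling step operates on sorted sequences, never on raw set
iteration order, so outputs are byte-identical across platforms and
processes.

## Simulation design for the property checks

Problem sizes were chosen so each check isolates the property it tests:

* **Similarity oracle**: 1,000 random pairs over universes ≤ 30 against an
  element-enumeration oracle (tolerance 1e−12).
* **Fisher oracle**: every margin with universe ≤ 12 against exhaustive
  enumeration of all C(N,q) draws (tolerance 1e−10).
* **Type-I calibration**: 1,000 null queries of 200 genes against 200 sets
  of scales 200–500 at universe 1,000; observed rejection fraction at 0.05
  compared with binomial 99% bounds using the replicate count as the trial
  count (set-level rejections within a replicate share one query and are
  positively dependent). Large sets and a large query are deliberate: the
  exact hypergeometric test is conservative when its discrete support is
  coarse — with scale-20 sets the exact null rejection probability at
  nominal 0.05 is as low as 0.013 (computable in closed form), for any
  correct implementation — so calibration is assessed where the null is
  near-continuous.
* **Enrichment recovery**: 100 planted queries (30 in-target + 70
  background) at universe 1,000 over 200 sets of scales 10–100.
* **Prioritization recovery**: 100 replicates at universe 5,000, 100 sets
  of scales 20–50, effect 3×.
* **GSAN agreement**: 30-set fixtures per overlap model against full pair
  enumeration under identical thresholds.
* **Scale fit**: exact scale^(−2) law over scales {1, 10, 100} (slope −2,
  R² = 1 analytically) and a noisy seeded power law over ~150 distinct
  scales (recovered exponent within ±0.1).

## Known limitations

* Set similarity is purely membership-based; no network-distance or
  semantic similarity between sets.
* The enrichment module implements over-representation only — no
  running-sum (GSEA-style) or topology-aware statistics.
* The Fisher universe is a single scalar; per-source or annotation-aware
  backgrounds are not modeled.
* Organism labels are carried but no cross-organism mapping is performed;
  symbol unification relies on the user-provided alias map.
* The scale-distribution fit is OLS on logs, with the usual caveat that it
  is biased as a power-law estimator compared to maximum likelihood.
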