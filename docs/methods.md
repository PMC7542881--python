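# Methods

## Problem and model

After gene-set analysis, the unit of interest is a *collection* of named
gene-sets with provenance (tool, experiment, species, p-value). All
statistics are functions of gene membership only: for sets *i*, *j* the
sufficient statistics are the overlap C<sub>ij</sub>, the sizes
P<sub>i</sub>, P<sub>j</sub> and the universe size N. Three similarity
metrics are implemented from these counts:

* **Relative risk** (default): RR<sub>ij</sub> = C·N / (P<sub>i</sub>P<sub>j</sub> − C).
  RR is 0 when C = 0; its denominator vanishes only for two identical
  singleton sets, where the value is a +∞ sentinel replaced at matrix level
  by the largest *finite off-diagonal* score (the replacement count is kept
  on the matrix and surfaced in exports). The diagonal uses the same
  formula, RR<sub>ii</sub> = N/(P<sub>i</sub> − 1); diagonal infinities are
  replaced too but excluded from the replacement statistic so self-similarity
  cannot distort it.
* **Jaccard**: C / (P<sub>i</sub> + P<sub>j</sub> − C), in [0, 1].
* **Cohen's kappa**: chance-corrected agreement of the two membership
  indicators over the universe, in [−1, 1], with κ = 1 by convention when
  the expected agreement is 1 (both sets equal the whole universe).

The universe N defaults to the union of genes in the loaded sets; an
explicit measured background can be supplied and flows through every
computation. Both choices are defensible — the default requires no extra
input, the override is more faithful when the assay's background is known.

## Harmonization

Identifier translation is table-driven: (source_id, namespace, species) →
target symbol, loaded from a 4-column TSV. Gene tokens are stripped and
uppercased at ingest (case is the dominant symbol inconsistency), so lookups
are case-insensitive on the source side. Many-to-one mappings collapse to
one token (set semantics); one-to-many mappings expand to all targets, with
both events counted in the harmonization report. A token that already
equals a known target symbol for its species is treated as mapped to itself;
this pass-through rule is what makes harmonization idempotent under either
unmapped policy ("keep" uppercased verbatim — the default, because silent
dropping biases overlap counts — or "drop"). Redundancy reduction collapses
sets with identical gene content only within one (experiment, tool) pair,
keeping the lexicographically smallest name and recording aliases; identical
content from different experiments is deliberately kept.

## Clustering

K-means operates on the rows of the similarity matrix, i.e. each gene-set is
described by its similarity profile to every set. Lloyd's algorithm is
implemented in-package with seeded random-point initialisation, a fixed 25
restarts, a per-iteration assertion that the within-cluster sum of squares
never increases, and the rule that a restart ending with an empty cluster is
discarded (an error only if all restarts fail). scikit-learn's KMeans is
used in the test suite as an independent cross-check, never as the
implementation.

Hierarchical clustering runs average linkage (configurable: complete,
single, or ward on the feature rows) on a bounded monotone dissimilarity
transform: 1 − s for Jaccard, (1 − s)/2 for kappa, and 1 − s/max(s) for RR
and custom metrics (after capping, when a cap is used). The tree is cut
with `cut_tree`, which yields exactly k clusters even when merge heights
tie. Labels are canonicalised to 1..k by decreasing cluster size, ties
broken by the smallest member set_id, so outputs are identical across
platforms and input orderings.

Model selection (`optimal_k`):

* **silhouette** — mean silhouette width of the k-means partition computed
  on the dissimilarity matrix; recommend the argmax.
* **elbow** — within-cluster sum of squares per k; "the elbow" is
  operationalised as the k of maximum curvature (largest second difference),
  which needs at least three k values; the full curve is always returned so
  a user can override.
* **gap** — Tibshirani's gap statistic with B uniform reference draws over
  the bounding box of the feature rows; SE(k) = sd·√(1+1/B); recommend the
  smallest k with Gap(k) ≥ Gap(k+1) − SE(k+1), falling back to the largest
  tested k if no k satisfies the rule. Reference fits use fewer k-means
  restarts (5, vs 10 for the observed data inside model selection) since
  only the dispersion of log W under the null is needed; the clustering
  itself always uses the full 25.

The highlight score of a set is |genes ∩ subset| / |genes|, and a cluster's
score is the mean over members — a simple, interpretable fraction chosen
because no standard definition exists. Per-cluster gene summaries are exact
set algebra: shared = intersection over members, unique = union of members
minus the union of all other clusters.

## Over-representation analysis

Cluster gene lists (all member genes, or cluster-unique genes) are tested
against an annotation GMT with the one-sided hypergeometric tail
P[X ≥ k] and Benjamini–Hochberg adjustment within each cluster. The
universe is the union of the data and annotation universes — conservative,
and overridable. This is a deterministic, offline interpretation step; no
web enrichment service is involved.

## Visualisation and export

The network view draws an edge for every unordered pair whose similarity is
*strictly above* the threshold (so a pair exactly at the threshold is not
connected); isolated nodes are kept. The edge list, not the rendered
layout, is the tested artifact; layouts are seeded force-directed. The
heatmap orders rows by (cluster label, set_id) — a pure function of the
clustering — and a cap (e.g. RR capped at 70) bounds the colour scale only.
The threshold is applied to raw, uncapped scores. Dendrograms export their
merge structure as newick text so topology is testable. All tabular exports
are UTF-8 TSVs with '.' decimals and no index column; floats are printed via
`repr`, which round-trips bit-exactly, and re-running any stage with the
same seed reproduces every TSV byte-for-byte.

## Synthetic data

The planted-partition generator emulates the situation the package targets:
groups of gene-sets with high mutual gene overlap. Each of `n_groups`
groups owns a private pool (`pool_size` genes, pools disjoint); a set draws
`round(within_overlap · set_size)` genes from its pool and the rest from a
shared background, without replacement. Defaults — 3 groups × 8 sets,
set size 20, pools of 40, 90 % within-pool draw, background 200 — give
clearly separated groups whose between-group overlap arises only through
the background; its expected Jaccard index is computable exactly from the
hypergeometric law and is verified against the empirical mean. The
generator does not mimic real term-size distributions, term nesting (GO's
hierarchy), or correlated annotation — so passing recovery tests shows the
machinery is correct on separable structure, not that real GSA output is
this separable. The number of background-draw collisions, not biological
signal, controls the noise floor. One integer seed drives a single
generator stream.

## Problem sizes and numerical choices

Tests and the acceptance script use the default 24-set design, 20 seeded
replicates for recovery statistics and B = 50 gap references — sizes chosen
to make the statistics stable while keeping a full run in seconds on one
CPU. Floating-point comparisons in tests use relative tolerance 1e-9
(metric oracles) and exact equality where determinism is the contract.
Matrix symmetry is enforced by averaging with the transpose (guarding
against float noise in vectorised paths) and checked to 1e-12.

## Known limitations

* No semantic (ontology-graph) similarity and no PPI-weighted distances:
  similarity is purely gene-content overlap by design.
* The RR→dissimilarity transform depends on the matrix maximum, so adding
  sets can rescale hierarchical distances; Jaccard/kappa transforms are
  absolute.
* ORA assumes annotation terms and data share one harmonized vocabulary;
  tokens outside the joint universe are ignored.
* IPA/GREAT parsing targets the dialects defined by the bundled fixture
  writers; other export versions are handled via the column-mapping
  override, not auto-detected.
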