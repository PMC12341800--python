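# Methods

This note documents the models, defaults and numerical choices behind
`consig`, and what the synthetic-data tests do and do not demonstrate.

## Marker filtering

A marker record passes when its fold change exceeds the threshold
*strictly* and its adjusted p-value is *strictly* below the cutoff
(defaults: linear FC > 1.5, p.adj < 0.05).  Fold-change scales are
per-study: LOG2 values are back-transformed (2^fc) before comparison,
while studies reporting natural-log fold changes are thresholded directly
at ln FC > 0.25, mirroring how such lists are published.  A missing
p.adj is treated as failing any p threshold — the conservative reading,
since an unreported significance cannot support inclusion.  Records with
unparseable fold changes are rejected with their line numbers; empty
filtered lists are legal and kept as units (they deflate similarity
rather than silently disappearing).

Gene symbols are matched case-insensitively after whitespace trimming,
with the first-seen spelling preserved; no alias or ortholog resolution
is attempted, because symbol rewriting would silently change every
overlap count downstream.  Merges of variant spellings are logged.  A
consequence is that typo-like variants in published lists (e.g. a
"Cdks6" spelling) stay distinct from their likely intended symbol.

## Similarity, distance and clustering

For gene lists *A_i*: common-count |A_i ∩ A_j|, Jaccard
|∩|/|∪|, and overlap coefficient |∩|/min(|A_i|, |A_j|).  The default
pipeline path is Jaccard with d = 1 − s: it is scale-free, which matters
because published marker lists differ by an order of magnitude in size.
The common-count metric with d = max(S) − s is provided to mirror the
literal "number of common genes" construction.  Pairs with an empty
union (two empty lists) get similarity 0 with a warning.

Agglomeration is implemented directly (Lance–Williams updates for
single, complete and average linkage) rather than delegated, so the
tie-break can be fixed: among minimum-height candidate merges, the pair
whose lexicographically smallest leaf label sorts first wins, then the
other cluster's smallest label.  This makes dendrograms reproducible
across platforms even on degenerate inputs (identical lists).  On
tie-free inputs the result is verified against an independent
hierarchical-clustering implementation via cophenetic distances.  The
problem sizes here are tens of populations, so the O(n³) scan is
irrelevant to runtime.  Complete linkage is the default (the common
default of the R routine used for such analyses); heights are
non-decreasing for all three linkages offered.

## Exclusive intersections and consensus

Each union gene belongs to exactly one membership pattern (the exact
subset of lists containing it), so pattern counts sum to the union size —
the invariant behind UpSet plots.  The consensus signature at threshold
*k* is the set of genes appearing in ≥ k distinct units, ordered by
descending unit count then symbol.  The counting unit defaults to STUDY
(a gene counts once per study even when several of that study's clusters
list it); CLUSTER counting is available where per-cluster resolution is
wanted.  Consensus sets nest monotonically in *k* by construction, and
both operations are tested against brute-force per-gene enumeration.

## Signature scoring

**Z-score method.**  Each signature gene is standardized across cells
with the sample (n−1) standard deviation; the per-cell score is the mean
z over genes.  Zero-variance genes are dropped with a warning (imputing
them would shrink every score toward 0 by a data-independent amount).
This is the method used for pseudotime profiles, where cross-study
comparability of the *shape* matters more than the absolute level.

**Capped-rank method.**  Within each cell, all genes are ranked by
decreasing expression with average ranks on ties; ranks beyond
`max_rank` are truncated to `max_rank + 1`; the score is
1 − U′/(n_s·max_rank) with U′ = Σ ranks − n_s(n_s+1)/2, clipped to
[0, 1] (clipping events are counted and logged).  `max_rank` defaults to
1500, the published default of the rank-scoring tool this reproduces; it
is exposed because the statistic's scale depends on it.  The main
engineering subtlety is sparsity: all zero-expression genes of a cell tie
at one large average rank, which the cap truncates, so unexpressed
signature genes contribute exactly the worst admissible rank — this case
is unit-tested by hand.  Because the score depends only on within-cell
ranks, it is invariant under any strictly monotone per-cell transform,
hence insensitive to library-size normalization.  With `max_rank` equal
to the gene count G, a random signature of size n_s has expected score
exactly 1/2 + n_s/(2G), which the tests check empirically.

Scores are computed on log-normalized expression; raw counts are first
converted to log1p counts-per-10k (logged when it happens).  The
high-cell cutoff (default 0.4) is inclusive (≥); the cutoff is applied
to raw scores, not within-dataset-rescaled ones.

**Dot-plot summaries.**  Per (gene, cluster): percent of cells with
expression > 0 and mean expression over all cells of the cluster (zeros
included).  `marker_specificity` quantifies restriction as the target
cluster's percent-expressed minus the best other cluster (range −100 to
+100), the quantity behind claims that a marker is population-specific.

## Pseudotime profiles

Pseudotime is consumed as given — the package never infers trajectories;
upstream tools differ and the comparison should not. Profiles are
per-bin means of the per-cell score over equal-width bins spanning the
observed pseudotime range (default 50 bins).  Empty bins propagate as
missing, never zero.  An optional centered rolling mean over bin means is
off by default: raw bin means are the reproducible primitive, smoothing
is cosmetic.  The trend statistic is the Spearman rho between bin centers
and non-empty bin means (≥ 3 non-empty bins required); |rho| < 0.3, or an
undefined rho on constant profiles, classifies as FLAT.  Module overlap
counts signature genes per module; genes in several non-disjoint modules
count in each and are listed, and with disjoint modules the counts plus
the unassigned remainder partition the signature exactly.

## Synthetic data

The marker generator emulates the structure of the real cross-study
comparison: seven studies, each class carrying a small shared core
planted in a configured number of studies plus ~200 study-private genes,
and 30 decoy records per study drawn to fail the filter (half by low
fold change, half by non-significant p).  The default presence plan
places 28 NSC core genes at ≥ 5 of 7 studies with 2 in all seven, 62 NP
core genes at ≥ 3 with 10 in all seven, and a 20-gene neuroblast core at
≥ 3; where the published analysis fixes only the totals, the remainder is
split evenly across the remaining presence levels.  One study reports
natural-log fold changes to exercise that filter path.  Planted fold
changes draw from U(1.8, 4) linear (U(0.35, 1.2) ln) with p.adj from
U(10⁻⁶, 0.01) — comfortably inside the thresholds, as published lists
are post-threshold.

The expression generator draws pseudotime t ~ U(0, 1) per cell and
negative-binomial counts with mean μ = baseline × trend factor
(DECREASING: 1 + a(1 − t); INCREASING: 1 + a·t; FLAT: 1) and variance
μ + μ²/θ.  Defaults: 2000 genes × 2000 cells, baseline mean 0.5
counts/gene (sparse, scRNA-seq-like), dispersion θ = 2, program
amplitude a = 5 for the 50-gene quiescence (declining) and activation
(rising) programs — a strong, cleanly recoverable trend — and a 125-gene
flat senescence program sized like the SenMayo set.  A 20% senescent
subpopulation multiplies its senescence-program means by 4.  A
log1p-counts-per-10k layer is emitted alongside counts.  All draws pass
through one seeded NumPy generator, so outputs are bit-reproducible.

What this emulates — and does not.  The generator reproduces the
*structure* the pipeline exploits (shared cores, monotone programs, a
mean-shifted subpopulation) with idealized nuisance: no library-size
gradients, batch effects, doublets, ambient RNA, per-gene dispersion, or
branching trajectories, and decoys fail the filter by construction
rather than borderline noise.  Passing tests therefore demonstrate that
the implementation recovers known truth under its stated model, not that
the thresholds or scores are optimal for any real dataset.

## Problem sizes and defaults in the test suite

The automated checks run the marker simulation at full scale (7 studies,
~5400 records), the expression fixture at 2000 × 2000, the analytic
rank-score check at G = 2000 with 500 random-signature draws, and the
brute-force oracles at ≤ 6–8 lists × ≤ 100 genes over hundreds of random
instances; the whole suite completes in well under a minute on one core.

## Known limitations

- No alias resolution means symbol variants count as distinct genes.
- The consensus is unweighted: a gene at FC 10 in five studies and one at
  FC 1.6 in five studies are equivalent; fold-change-aware weighting is
  deliberately out of scope.
- Dendrograms carry no bootstrap support values.
- Trajectory inference, RNA velocity, GO summarization and cell–cell
  communication analyses are out of scope; precomputed embeddings are
  carried through the annotation only.
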