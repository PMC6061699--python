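# Methods

`litnet` turns sentence-level co-mentions of chemicals, genes and diseases
into a thematically labeled, weighted relationship network. This note
describes the model behind each stage, the parameters that matter, the
numerical conventions, and what the synthetic test bed does and does not
establish about behaviour on real literature.

## The pattern unit: dependency paths

The atomic observation is a *dependency path*: the chain of
(governor, relation, dependent) triples along the unique tree path between
two entity tokens in a sentence's dependency parse, with the two entity
lemmas masked as `START_ENTITY` / `END_ENTITY` and all other lemmas
lowercased. Masking makes the path a reusable *pattern* — "X is a potent
inhibitor of Y" and "A is a potent inhibitor of B" yield the same path —
and it is these patterns, not the sentences, that get clustered and scored.

Ingest conventions:

* Offsets are 0-based and end-exclusive into `title + " " + abstract`.
  The reader validates every mention's surface string against the text at
  its offsets and rejects mismatches rather than guessing.
* Multi-word mentions are concatenated with underscores before alignment;
  whitespace runs collapse to a single underscore and downstream offsets
  shift accordingly. A mention must then correspond to exactly one parse
  token; mentions the tokenizer split are skipped with a warning. Tokens
  are matched by form equality (with order-based disambiguation for
  repeated surfaces), which tolerates tokenizer artifacts such as
  `-LRB-`/`-RRB-` that break character-level alignment.
* Overlapping mentions: keep the longest, ties to the earliest start.
* Paths are extracted in a fixed type orientation (chemical→gene,
  chemical→disease, gene→disease); direction of meaning is carried by the
  themes instead. Gene–gene sentences have no natural orientation, so
  both directions are extracted.
* Paths crossing a coordinating-conjunction dependency (`conj` or any
  `conj:*` subtype) are discarded; parsers encode lists with these edges
  and the resulting paths rarely express a relationship.

## The incidence matrix

For each relationship type, a binary matrix with entity pairs as rows and
paths as columns: cell (i, j) is 1 iff path j connects pair i anywhere in
the corpus. The clustered vocabulary keeps the most frequent paths
(`top_n_paths`, default 700; ties at the cutoff break lexicographically;
`min_path_occurrence`, default 50, floors eligibility), and
`n_pairs_sampled` rows (default 2000) are drawn uniformly without
replacement from the pairs connected by at least one vocabulary path. The
sample is uniform rather than stratified — the simplest defensible choice
where the sampling scheme is not otherwise pinned down. All-zero rows and
columns are dropped before clustering.

## Co-clustering ensemble

The base learner is information-theoretic co-clustering (ITCC): normalize
the matrix to a joint distribution p(X, Y), and alternately reassign rows
and columns to minimize

    KL( p(X,Y) || q(X,Y) ),    q(x,y) = p(x̂,ŷ) p(x|x̂) p(y|ŷ),

which equals the mutual-information loss I(X;Y) − I(X̂;Ŷ). One sweep
updates all rows, then all columns; iteration stops when the objective
improves by at most `tolerance` (1e-9) or after `max_iterations` (25)
sweeps. The objective is non-increasing across sweeps.

Numerical conventions: 0·log 0 = 0; argmin ties break to the lowest
cluster index; an initial assignment that leaves a cluster empty is
redrawn (the batch update can never repopulate an empty cluster), but
clusters that empty out during iteration stay empty.

Two implementation choices matter beyond the textbook algorithm:

* **Exact-objective polish.** The batch sweeps stall in fixed points that
  a single row or column move would improve. After convergence, a
  steepest-descent stage applies single-element moves evaluated on the
  exact objective — only I(X̂;Ŷ) changes when one element moves, so each
  candidate costs O(KL). On exhaustive-enumeration benchmarks (5×4
  binary matrices, K=L=2) the batch algorithm alone misses the global
  minimum on roughly one matrix in ten; with polish, the best of 20
  restarts matched the enumerated minimum on every instance tested.
* **Canonicalized order.** Fits are run on a canonical row/column
  ordering (color refinement with content tie-breaks) and mapped back, so
  the ensemble is exactly equivariant under column permutations;
  byte-identical columns share their batch updates and are moved jointly
  during polish, so they always co-cluster.

The ensemble repeats the fit `n_runs` times (default 2000, matching the
procedure at full scale; the tests and acceptance runs use 20–50, which
is already enough to recover planted structure at their problem sizes)
with seeds `base_seed + run_index`, at fixed (K, L). Per-type (K, L)
defaults are shipped as (100, 100), (150, 170), (190, 150) and (90, 70)
for chemical-gene, chemical-disease, gene-disease and gene–gene; the
grid-selection heuristic `select_kl` scores each grid point by ensemble
stability — mean |f − 0.5| over off-diagonal co-clustering frequencies f
on a small pilot ensemble — preferring configurations whose co-assignments
are confident rather than coin-flips. This criterion is this package's
own substitute for an upstream heuristic that is not fully specified.

## Dendrograms

The ensemble's output is the count, for every pair of paths, of runs in
which they shared a column cluster. Frequencies f = counts / n_runs are
compared by Pearson correlation of whole frequency rows (the self-column,
constant 1, is kept; it shifts all correlations equally), giving the
distance d = 1 − r ∈ [0, 2]. Constant rows carry no information and get
correlation 0 (distance 1) by convention, logged.

Hierarchical clustering uses **minimax linkage**: the distance between
clusters G and H is min over prototypes c ∈ G∪H of max over x ∈ G∪H of
d(c, x) — the smallest covering radius of the union. Every cluster in the
tree therefore has a concrete prototype path within merge height of all
members, which is what makes clusters reviewable by reading
representatives. Merge ties break toward the smallest cluster-id pair.
Minimax linkage is not guaranteed monotone; heights are reported as
computed, and cuts are defined by merge order (undo the last k−1 merges),
which is well defined regardless of height order.

Defaults mirror the full-scale procedure: cut at 30 clusters, discard
clusters of 10 or fewer paths, sub-cut large clusters via a per-cluster
configuration, and sample 10 paths plus example sentences per cluster
into a review sheet for human labeling.

## Themes, flagship paths, supports

Human annotators label clusters with theme symbols; the packaged schema
carries 10 chemical-gene, 7 chemical-disease, 10 gene-disease and 9
gene–gene themes, including reverse-direction themes (e.g. O, K, Z read
gene→chemical) and manually sign-split expression/activation families
(E+/E−/E, A+/A−). Sign overrides move individual paths between variants
of a family.

The labeled vocabulary paths are each theme's *flagship paths*. Every
corpus path p (vocabulary or not) gets a raw support per theme t:

    support(p, t) = #{ (entity pair, f) : f ∈ flagships(t), f ≠ p,
                       both p and f connect the pair }

counted over the full (all-paths) incidence. A flagship path does not
count itself — otherwise every flagship's own-theme support would be
inflated by exactly its pair count. Counting (pair, flagship)
combinations rather than distinct pairs or sentence repeats is consistent
with the binary incidence. Normalized scores divide by the row total and
sum to 1; paths with zero total support cannot be scored and are excluded
from the path–theme table.

## Enrichment evaluation

A reference relation set (a two-column entity-pair TSV, strings
normalized by lowercasing and underscore-concatenation) supplies
positives; the background is every corpus pair of the same relationship
type with at least one scoreable path, minus the positives. Per bootstrap
replicate, both sets are resampled with replacement at their original
sizes; every path connecting a sampled pair enters the ranking once per
draw of that pair (standard bootstrap semantics — a pair drawn twice
contributes its paths twice); path instances are ranked by the theme's
normalized score and scored by Mann–Whitney AUC (ties credit 0.5) against
the positive/background labels. Replicates that draw a single class are
redrawn and counted. Over `n_boot` replicates (default 100) the mean and
standard deviation (ddof = 1) are reported, and a theme is *enriched*
when mean > 0.5 + sd, strictly.

Because a non-matching theme's own pairs sit in the background and score
high on that theme, non-matching themes typically produce AUCs well
*below* 0.5 — enrichment is a sharper signal than a null of 0.5 would
suggest.

## Synthetic test bed

The generator plants known structure: each latent theme owns a set of
dependency-path templates (two syntactic frames, verb-object and
copular-nominal, with theme-specific keywords) and a set of typed entity
pairs; each pair is connected by a random subset of its theme's templates
(`sightings_per_pair`, default 3 of 10), and each sighting adds a random
other-theme sentence for the same pair with probability ε (default 0.05).
Sentences are emitted as PubTator blocks with gold CoNLL-U parses —
template realizations, not parser output — so tests are hermetic. About a
quarter of entity surfaces are multi-word to exercise underscore
concatenation. Defaults (4 themes × 10 templates × 30 pairs, ~360–400
sentences) keep a full pipeline run to a few seconds on one CPU.

At ε = 0 the pair×path incidence is exactly block-diagonal under the gold
ordering, and the pipeline must recover it perfectly (ARI = 1, every
path's argmax theme equal to its gold theme); at ε = 0.05 recovery must
stay above ARI 0.8 and reference sets drawn from one theme's pairs must
enrich that theme and no pair-disjoint theme. The planted-matrix
generator plays the same role at the matrix level (block-constant
patterns with Bernoulli cell flips, pattern redrawn until block-rows and
block-columns are distinct so the structure is identifiable).

What passing these tests does *not* show: robustness to parser error and
entity-recognition noise, to the heavy-tailed path frequency
distributions of real Medline, to themes of very unequal size, or to the
orphan-path problem (paths that never co-occur with any flagship path
remain unscoreable by construction). The generator plants clean
low-dimensional structure; real corpora are messier in all four ways.

## Known limitations

* The exact-objective polish makes each fit O(elements × clusters) per
  move; at full scale (700 columns, K ≈ 100, 2000 runs) the ensemble is
  compute-heavy and intended for batch execution.
* Scoring by flagship co-occurrence cannot reach paths whose entity pairs
  never meet a flagship path; coverage on real corpora is therefore
  partial by design.
* Theme labeling is human work; `label_clusters_by_gold` is a stand-in
  used only on synthetic corpora where gold labels exist.
* Minimax linkage is quadratic in memory and cubic in time in the number
  of clustered paths; it is run on the capped vocabulary, never the full
  path set.
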