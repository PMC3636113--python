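# Methods

## Expression tiers

Genes are classified per condition from unique-read counts over biological
replicates (any replicate number ≥ 1; the generators default to 3). The
tier is a function of the maximum replicate count *m*:

| tier | rule | default cutoffs |
|---|---|---|
| NOT_EXPRESSED | *m* = 0 | — |
| LOW | 0 < *m* ≤ `low_max` | `low_max` = 10 reads |
| HIGH | *m* > `high_min` | `high_min` = 2000 reads |
| MEDIUM | otherwise | — |

Verbal definitions of the form "≤ 10 in either replicate" and "> 2000 in
either replicate" are ambiguous — a gene with replicates (5, 3000, 0) would
satisfy both. Classifying on the maximum is the design choice here: it
yields a mutually exclusive, exhaustive partition (every gene gets exactly
one tier, the tier depends only on the multiset of counts), and it agrees
with the verbal rule whenever the verbal rule is unambiguous. Counts must
be non-negative integers; anything else is rejected rather than coerced.

## Differential expression

Counts are scaled to counts-per-million (each sample column sums to 10⁶;
a zero-total sample is an error naming the sample). The per-gene test is a
two-sided two-sample *t*-test on log₂(CPM + 1):

* **log scale** — chosen for variance stabilization of overdispersed
  counts; the raw CPM scale is available via `log_scale=False`.
* **pooled variance** (Student's test) by default, matching the named test
  of the original protocol; Welch via `welch=True`.
* **no multiple-testing correction** by default, matching the raw
  *P* < 0.05 filter such protocols use; Benjamini–Hochberg via
  `bh_correction=True` (the BH-significant set is always a subset of the
  raw-significant set at equal alpha).
* the p-value is **undefined** (`None`, not 1 or 0) when both groups are
  constant — this covers genes with all-zero counts.

Condition ratios accompany every record. The primary ratio is the ratio of
mean CPMs. Because "ratio of means" versus "mean of per-replicate ratios"
is a genuinely open choice, both are reported: `ratio_mean ± ratio_sd`
summarises per-replicate-pair ratios, paired by replicate index, and is
only defined when replicate numbers match and every reference replicate is
positive (otherwise a pair ratio would be infinite). Special cases:

* all reference replicates zero, any treatment read → **DE_NOVO**
  (rendered as `DE_NOVO` in tables, the analogue of an infinite ratio);
* all replicates zero in both conditions → **undefined** (`NA`).

The alpha that defines the reported DE set is a parameter (`de_alpha`,
default 0.05). Where downstream summaries are filtered at 0.01 instead,
that is a reporting threshold on the same records, not a different test.

## Co-expression networks

Correlations are computed over a normalized samples × genes compendium
(finite values enforced at load; at least 3 samples). Design choices:

* **Signed threshold, inclusive**: edge iff *r* ≥ 0.7 (exactly 0.7 is an
  edge). Co-expression modules of interest here are positively
  co-regulated; `absolute=True` switches to |*r*| ≥ threshold.
* **Constant genes** have undefined correlations; they are dropped from
  network construction with a logged warning rather than raising, because
  a flat probe in a large compendium is expected, not exceptional.
* **Isolated guides are not nodes**: a gene enters the network only
  through a retained edge, so node counts are typically far below the
  input-list size.
* **Missing compendium values are rejected at load time** — no
  pairwise-complete correlation — which keeps the brute-force oracle used
  in the tests exact.

Modules are the connected components, ordered by decreasing size with ties
broken by the lexicographically smallest member. Sub-module splitting
removes a set of connector genes from a module and returns the components
of the induced subgraph; the candidate connectors of a module are its
articulation points.

Bait–prey ("fishing") networks take all pairs over baits ∪ preys above the
threshold and drop prey–prey edges, so retained preys ("fished" genes) are
exactly those correlated with a bait. An id appearing in both lists counts
as a bait (baits come from a prior network and take precedence). The
bookkeeping identity `nodes = retained baits + fished preys` holds by
construction and is asserted over random designs in the tests. Bait–bait
edges are recomputed at the same threshold, not inherited from any earlier
network.

Exports: SIF (`geneA co geneB`), GraphML (node attributes `role`,
`direction_tag`; edge attribute `r`, six decimals) and edge-list TSV. All
writers emit nodes lexicographically and edges by (min id, max id), so
identical networks give byte-identical files.

## Enrichment

Upper-tail hypergeometric (one-sided Fisher) per term, uncorrected at
*P* < 0.01 by default, BH by flag; only terms overlapping the query are
reported; the background defaults to the annotated genes of the table and
can be overridden (e.g. restricted to compendium genes). The annotation is
flat — no ontology-hierarchy propagation.

## Synthetic data

The generators are pure functions of their config (seed included) and
write the same text formats the pipeline reads, plus a truth JSON.

**Counts.** Negative binomial per gene, mean/dispersion parameterization
(variance = μ + φμ², φ = 0.1 by default), the standard overdispersion
model for RNA-seq counts. Default tier composition (8% silent, 9% low,
78% medium, 5% high) and DE fraction (15%, of which 10% repressed) mirror
the composition observed in a root kinase/phosphatase transcriptome under
phosphate starvation; tier means default to 3 / 200 / 5000 raw reads and
the planted fold change to 8. After drawing, each reference-condition gene
is nudged into its planted tier bracket (values above the bracket are
clipped; if the maximum falls below the bracket, the largest replicate is
raised to the bracket floor). This guarantees the planted tier labels are
exactly recoverable — the point of a planted-truth generator — at the cost
of a slight truncation of the negative-binomial tails (negligible at the
default means: the medium tier's ±3σ range lies inside its bracket).
Non-DE treatment draws get the same nudge, so null genes stay exchangeable
between conditions; DE genes multiply the treatment mean by the fold
change (drawn from the medium tier, where a fold change is observable in
both directions); de novo genes are drawn from the silent tier with a
medium-mean treatment signal.

**Compendium.** Rank-1 latent-factor blocks: gene *g* of module *m* has
value *w·z_m + ε* with *z_m* ~ N(0, σ_z²) per sample and
ε ~ N(0, σ_ε²), giving the closed-form expected within-module correlation
*w²σ_z² / (w²σ_z² + σ_ε²)*, which the generator reports. The loading can
be set directly or derived from a target correlation (default 0.9).
Background genes are independent noise with the same marginal variance as
module genes. This is the simplest structure with an analytically known
correlation; it does not emulate array-platform effects, batch structure
or heavy-tailed expression, so passing tests demonstrate correctness of
the network machinery, not robustness to real-array artefacts.

**Annotation.** One term concentrated on a designated gene set plus
uniformly random filler terms (default size 10).

**Presets.** `tiny` (30 genes, 60 samples) for fast end-to-end checks;
`paper-scale` (1323 genes, ≈200 DE guides, a 22-gene bait module, 208
preys of which 75 share the bait module's factor, 300 samples) matching
the shape of the original study design. Problem sizes throughout the test
suite (2000 genes for calibration, ≤ 100 genes for oracle comparisons,
N ≤ 15 for exhaustive enumeration) were chosen so each check completes in
seconds while leaving Monte-Carlo error well below the asserted bands.

## Pipeline

Stages run in order: load → classify (reference condition) → differential
expression → guide network (guides default to the DE gene set, including
de novo calls; an explicit guide list overrides) → modules → bait–prey
fishing (baits default to the largest module) → enrichment (of the network
node set and of the fished set). Fishing and enrichment are skipped, and
recorded as skipped, when their inputs are absent. Node `direction_tag`s
(up / down / unchanged) come from the DE ratios. All outputs are plain
TSV/JSON; the run report contains per-stage counts recomputable from the
written files, input SHA-256 hashes, and wall-clock timings (the only
report fields excluded from determinism comparisons). Dropped or
reassigned gene ids are always logged to stderr, never silent.

## Known limitations

* The *t*-test with 3 replicates per group on log counts is only
  approximately calibrated; the acceptance checks bound its null type-I
  rate within Monte-Carlo error at n = 2000 genes rather than asserting
  exact uniformity of p-values.
* Connected components are the only community notion (plus articulation
  splitting); no modularity-based clustering.
* Per-million scaling is the only normalization; upstream processing
  (alignment, RMA, array curation) is out of scope and the compendium is
  consumed pre-normalized.
* The hypergeometric background is whatever gene universe the annotation
  table declares; results are sensitive to that choice, as with any
  over-representation analysis.
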