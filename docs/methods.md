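# Methods

`stepgrn` implements an integrative analysis of stepwise cellular
transformation in a three-stage isogenic design (a primary cell line, its
immortalized/pre-transformed derivative, and the fully transformed line).
The pipeline runs five stages — differential expression, promoter chromatin
states, TF/pathway association, epigenome–transcriptome integration, and
gene-regulatory-network (GRN) reduction — and ships a synthetic-data
generator with planted ground truth so that every stage has a
parameter-recovery test without any external downloads.

## Differential expression and co-expression pathways

Two comparisons are made against the first stage: step 1
(immortalized vs baseline) and step 2 (transformed vs baseline).  Per gene
and step, the fold ratio is the ratio of replicate means on the linear
scale; the test runs on log2 values.  A step call is `up` iff ratio > 2 and
p < 0.05, `down` iff ratio < 0.5 and p < 0.05, and `ns` otherwise.  A gene
is a DEG iff at least one step call is non-`ns`.  No multiple-testing
correction is applied by default, matching the fixed p < 0.05 gate; a
Benjamini–Hochberg option exists (`bh_correct`).

**Moderated Welch t.**  With two biological replicates per stage, the plain
Welch statistic is nearly powerless: its Satterthwaite degrees of freedom
hover near 2, where the 5 % critical value is 4.3, and per-gene variance
estimates on n = 2 are wildly unstable.  `call_degs` therefore shrinks each
group's sample variance toward a common prior (the mean per-gene variance
of that group across all genes) with `var_prior_df` pseudo-degrees of
freedom (default 8), augmenting the group degrees of freedom accordingly
before the Welch–Satterthwaite combination.  This is the standard
regularized-t device for replicate-starved expression designs.  When all
genes share a common noise level the moderated statistic is calibrated
(type-I error at the significance gate stays within binomial error of
alpha, verified on null simulations); `var_prior_df = 0` recovers the plain
Welch test, which the `welch_t` primitive exposes directly.

**Pathways.**  The two step calls give 3×3 − 1 = 8 informative patterns.
The default mapping collapses the two discordant-reversal patterns
(`up,down` and `down,up`) into one label, yielding the seven co-expression
pathways i–vii.  The mapping is configuration data
(`pattern_mapping`), not code, because the assignment of labels to patterns
is a naming convention.

## Promoter chromatin states

Five ChIP targets are profiled: H3K4me3, H3K9ac, H3K27ac (active marks),
RNA polymerase II, and H3K27me3 (repressive).  Coverage is read-count
intensity in non-overlapping 100-bp bins.  Normalization is two-step:
quantile normalization across the stages of one target (rank-mean
substitution; tied values receive the mean of the tied ranks' reference
values), then a z-transform per track so all targets share one scale and
z > 1.65 corresponds to the ~95th percentile on normal-like tracks.
Quantile normalization is exactly idempotent on tie-free data and
approximately so under tie averaging.

A mark is *present* at a TSS iff all three criteria hold:

1. a peak summit lies within ±500 bp of the TSS (both boundaries
   inclusive; coordinates are BED 0-based half-open; the window is
   symmetric, so strand affects only reporting);
2. the z-normalized summit-bin intensity exceeds 1.65;
3. the peak is robust under subsampling: the coefficient of variation
   (sd/mean) of the recovered peak intensity across binomially thinned
   replicates of the raw counts (fractions 0.9/0.7/0.5, 5 replicates each)
   is below 15 %.

The dispersion model operates on read counts, so deeper peaks are more
robust; dispersion is therefore not exactly invariant under intensity
rescaling (it can only decrease with depth), which matches the intent of a
sequencing-depth quality gate.  The subsampling protocol (fractions,
replicate count) is exposed in the configuration; randomness is seeded per
peak so evidence does not depend on evaluation order.  Broad-mark peak
files without a summit column use the interval midpoint.

**State taxonomy.**  With A = number of active marks present, P = Pol II,
R = H3K27me3, the classifier is total on all 32 combinations:

| state | rule (R absent) |
|---|---|
| active | P and A ≥ 2 |
| weakly_active | P and A = 1 |
| transcription_prone | no P and A ≥ 2 |
| ambiguous | exactly one active mark, or P alone |
| empty | nothing |

With R present: `repressed` when nothing else is there, otherwise
`bivalent`.  Eleven combinations pair H3K27me3 with only weak evidence (one
active mark alone or Pol II alone); these are classed bivalent by default
because bivalency semantics is repressive-plus-any-active evidence, but
`bivalent_closure=False` sends them to `ambiguous` instead.  Exactly seven
states exist and partition the input space (exhaustive test).

Presence is called with ±500 bp; median display profiles use ±1.5 kb,
oriented 5'→3' by strand — the two windows serve different purposes
(calling vs visualization).

**Transitions.**  A gene's trajectory is the ordered state triple across
the three stages; the transition-cluster id is the triple itself (at most
7³ = 343 clusters).

## TF/pathway association and integration

Candidate TFs must (a) cover strictly more than 10 % of some pathway's
DEGs (the pathway is the denominator) and (b) carry Pol II at their own
promoter in at least one stage (`pol2_stage` can pin a specific stage; the
choice of "any stage" is deliberate because the data do not dictate one).
Relevance is an upper-tail hypergeometric test of regulon/pathway overlap
in the expression universe — over-representation only, since the
association heat map encodes confidence of association, not depletion.
−log10(p) is capped at 300 to keep clustering distances finite.  Rows and
columns of the association matrix are ordered by agglomerative clustering
(average linkage, Euclidean distance; both configurable — the linkage
choice is a free parameter of the display, not of the statistic).

Chromatin-state clusters are integrated with pathways through a
contingency table over shared DEGs: expected counts under independence,
Pearson residuals (O − E)/√E (their squared sum equals the chi-square
statistic), and an enrichment flag at residual > 2.  Degenerate tables
(one row or column) return all-zero residuals with a warning.

Chromatin remodelers/modifiers (CRMs) are annotated by intersecting the
DEG set with a catalog of writer/eraser/reader/other genes, reporting the
step of change (step 1 only, step 2 only, both).

## GRN assembly and reduction

Three provenance layers over the DEG set: undirected interactions kept only
between DEGs; directed TF→target regulon edges for selected TFs with DEG
targets; directed oncogene→target edges for genes whose promoter (±1 kb,
configurable) holds an oncogene ChIP peak with −log10(p) ≥ 300.  Self-loops
are dropped; duplicates collapse within a provenance, while the same pair
may carry one edge per provenance.

Topological metrics run on the undirected skeleton (the metrics are
undirected notions; direction is an annotation here):

* **MNC** — size of the largest connected component induced by a node's
  neighbors;
* **DMNC** — |E|/|V|^ε of that component (ε = 1.7; ties between equal-size
  components break by edge count), 0 when MNC ≤ 1;
* **BottleNeck** — for each root, a breadth-first shortest-path tree is
  grown with deterministic sorted-neighbor ordering; a non-root node is a
  bottleneck of that tree when its subtree holds strictly more than a
  quarter of the tree's nodes; the score counts such roots.

Reduction keeps the union of top-`k_hubs` by MNC, top-`k_hubs` by DMNC and
top-`k_bottlenecks` by BottleNeck (ties by degree, then id) and returns the
induced subgraph with provenance preserved.  `k_hubs = 8` and
`k_bottlenecks = 6` by default, matching the planted structure of the
synthetic design; real data call for tuning these to the desired reduced
size.  Exports are SIF plus node/edge attribute tables (pathway segment,
per-step expression ratios, role), loadable in standard graph viewers.

## The synthetic-data generator

The generator emulates the statistical structure the pipeline assumes; it
is not a read-level simulator (no FASTQ, alignment, fragment-length or
copy-number modeling).

* **Genome**: one linear chromosome, TSSs every 10 kb (promoter and profile
  windows never interact), random strands.
* **Expression**: 2000 genes × 3 stages × 2 replicates by default; 4 % of
  genes per pathway (28 % DEGs overall — enough planted signal for stable
  recovery statistics while keeping most genes null); baseline log2 levels
  ~ N(7, 1.5); each planted change shifts the stage mean by exactly
  ±`effect_size` (1.5 log2 units ≈ 2.8-fold, a typical strong microarray
  effect); replicate noise ~ N(0, 0.25) on the log2 scale.  The constant
  effect magnitude realizes the configured mean |log2 ratio| exactly and
  keeps the fold gate's failure probability small and analytically
  predictable (≈ Φ(−2) per changed step at the defaults).  One fifth of
  pathway-ii genes realize the merged discordant pattern (`down,up`).
* **Chromatin**: every gene carries a planted state trajectory — a
  pathway-specific template for DEGs (e.g. bivalent→active→active for
  pathway i), a constant background state otherwise; driver TF genes are
  active at all stages so they can pass the Pol II filter, and half of the
  decoy TFs are deliberately Pol II-free to exercise it.  Each gene/stage
  emits the defining marks of its state jointly with probability
  `state_emission` (0.95); a failed emission drops all marks at that
  stage (the promoter reads as empty), so per-stage recovery is expected
  near the emission rate.  Planted peaks: summit within ±400 bp of the
  TSS, intensity from the upper 5 % tail of a gamma(2, 2); background
  peaks sit ≥ 2 kb from every TSS with bulk (5th–50th percentile)
  intensities at an ~3× smaller count scale, so the z > 1.65 gate separates
  planted from background by construction.  Coverage is Poisson counts on
  100-bp bins; H3K27me3 peaks are broad (1.5 kb, no summit column) to
  exercise the broad-peak dialect.
* **Regulons**: one driver TF per pathway plus decoys, hosted on non-DEG
  genes; regulon sizes ~ Poisson(30).  A driver draws 80 % of its targets
  from its pathway and the rest from non-DEGs, with the remainder capped so
  purity never falls below the planted guarantee (≥ 50 % in one pathway).
* **Interaction network**: DEGs are split into preferential-attachment
  communities chained by connector genes that are each the sole link
  between adjacent communities (removal disconnects them — the planted
  bottleneck truth).  The two end blocks each take ~29 % of DEGs so every
  connector separates the graph into two parts larger than a quarter of
  it, which is the regime in which the BottleNeck score singles the
  connectors out.  High-MNC hubs are planted as spoke-and-ring
  neighborhoods (the hub's neighbors form a 12-ring, so its MNC is 12
  against a background of ≤ ~4) and high-DMNC nodes as 4-cliques (a K4
  member's neighborhood is a complete K3, DMNC ≈ 0.46 against ≤ 0.31).
  In-pathway regulon and oncogene-ChIP targets are drawn from the
  community-tree *leaves of one home community*: leaves are mutually
  non-adjacent, so TF fan-in edges can neither manufacture spurious
  neighborhood components nor create inter-community shortcut paths that
  would distort the planted metric ranking.
* **Oncogene ChIP**: the pathway-vi driver acts as the oncogene (its
  targets change at the transformation step); its confident peaks
  (−log10 p ∈ [300, 500]) sit at designated target promoters, decoys are
  either sub-threshold at promoters or confident but mid-intergenic.
* **Determinism**: all randomness flows from one seed through named child
  streams; a seed fixes every output byte-identically.

What passing recovery tests show — and do not show.  The generator's noise
is homoscedastic, its effects are constant-magnitude, its background peaks
are cleanly separated from planted ones, and its interaction communities
are trees with engineered hubs.  Recovery at ≥ 95 % under these conditions
validates the pipeline's logic (gates, taxonomies, rankings, reductions),
not its power on real data, where variance heterogeneity, mappability
artifacts, correlated replicates, and dense interactomes will lower every
recovery figure.

## Numerical choices and degenerate inputs

* Zero variance in both samples with equal means: p = 1 by convention;
  unequal means with zero variance: p = 0.
* Fold ratios guard against division by zero with a 1e-12 floor; log2
  transforms add 1e-9.
* `welch_t` requires ≥ 2 values per sample; zero-variance tracks refuse
  the z-transform; empty coverage refuses a dispersion estimate
  (treated as infinitely dispersed when attached to a peak).
* Hierarchical-clustering leaf orders come from SciPy's deterministic
  linkage on a fixed input order; single rows return trivially.
* Reduction with k ≥ node count returns the full graph with a warning.
* Problem sizes: tests run the full pipeline at 250–600 genes with
  proportionally scaled planted structure (`SimulationConfig.scaled`);
  recovery acceptance runs the default 2000-gene design, which covers a
  20 Mb toy genome in 100-bp bins across 15 tracks.

## Known limitations

* The moderated-t prior assumes roughly exchangeable per-gene variances;
  strongly heteroscedastic data would need an empirical-Bayes prior fit
  rather than the mean-variance plug-in.
* Peak calling itself is consumed, not performed; garbage peak files yield
  garbage presence calls.
* The BottleNeck score depends on the documented sorted-neighbor BFS
  tie-break; other tree constructions give different (equally defensible)
  scores.
* Chromatin-state recovery is reported per gene-stage; trajectory-level
  recovery is necessarily lower (three chances to miss).
* The CLI covers the single-chromosome, one-TSS-per-gene case; multi-
  transcript genes require pre-collapsing the annotation to one TSS per id.
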