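# Methods

This note records the models, parameter choices, and design decisions behind
`enhancerstate`, and what the synthetic benchmark does and does not show.

## Coordinate conventions

All coordinates are 0-based half-open (BED native); all internal arithmetic
uses this convention. "Overlap" between intervals means ≥ 1 shared base
everywhere; a larger minimum can be requested (`min_bp`) where a stricter
criterion is wanted. Strand is carried on intervals but ignored by overlap
logic, since ChIP-seq peak coordinates are unstranded.

## Island calling

The caller follows the broad-domain (SICER-style) model: Poisson background,
eligible windows, gap-bounded islands.

* **Window / gap**: 50 bp / 50 bp defaults — the standard setting for broad
  chromatin marks and reader proteins. The gap must be a multiple of the
  window so islands stay on the window grid.
* **Tag preprocessing**: redundancy filtering keeps at most one tag per
  identical (position, strand) by default (`redundancy_threshold`),
  suppressing PCR duplicates; each retained tag is shifted by half the
  fragment size (default 250 bp, the midpoint of a typical 200–500 bp
  sonication range) toward its 3′ end to approximate the fragment midpoint.
* **Eligibility**: a window is eligible when its count *k* satisfies
  P(X ≥ k; λ) < 0.2 with λ the background expectation per window. λ uses an
  effective-genome fraction of 0.8 (configurable) to account for unmappable
  sequence.
* **Score**: an island's score is the sum of −ln Poisson(kᵢ; λ) over its
  eligible windows — additive, non-negative, and finite.
* **Score threshold**: rather than the analytic E-value recursion of the
  original broad-domain caller, the threshold is calibrated by Monte-Carlo:
  ≥ 20 uniform background libraries of the observed depth are simulated
  (seeded), islands are called and scored, and the threshold is the pooled
  score at rank E·n_sims, so the expected number of background islands
  passing equals the E-value (default 100). This is simpler, directly
  testable (the calibration property is asserted in the suite), and
  equivalent within sampling error; the analytic recursion could later be
  added behind the same interface. An explicit `score_threshold` can be
  passed to bypass calibration, which the oracle-equivalence tests use.

## Knockout differential filter

Off-target antibody signal appears equally in control and knockout
chromatin, so each candidate island is tested one-sided for control
enrichment above the knockout: with pooled control count *c*, knockout count
*k*, and retained library sizes N꜀ and Nₖ, the p-value is
P(X ≥ c) for X ~ Binomial(c + k, N꜀/(N꜀+Nₖ)). The binomial test was chosen
over a Poisson-ratio approximation for exactness at low counts. P-values are
Benjamini–Hochberg adjusted across all islands; islands pass at q < 10⁻³ by
default, with a stricter q < 10⁻¹⁰ preset (`kofilter.preset = "mll34_ko"`)
for contrasts against writer-knockout data where a harder cutoff is
conventional. Islands with zero total count are dropped with a log notice.

Controls are pooled for the differential test, and replicate-level island
sets are intersected afterwards; both orders are defensible, and this one
keeps the per-replicate island coordinates intact for the intersection step.

## Replicate high-confidence regions

A replicate-1 island overlapping ≥ 1 replicate-2 island contributes the
merged union of the overlapping pair(s) ("union" mode, default — preserves
the full island extent); an "intersection" mode emits the shared footprint
instead. Output is merged and sorted, so high-confidence regions never
overlap one another.

## Element classification

Classification is driven entirely by a `ClassificationRules` value — the
rules are data, not code:

* *proximal* = region midpoint within 2,500 bp of any TSS (midpoint-to-TSS
  is stable under region-width variation; regions straddling the boundary
  take the promoter branch);
* proximal ∧ H3K27ac → **active_promoter**; proximal ∧ ¬H3K27ac →
  **silent_promoter**;
* distal ∧ (H3K4me1 ∨ H3K4me2) ∧ H3K27ac → **active_enhancer**;
* distal ∧ (H3K4me1 ∨ H3K4me2) ∧ ¬H3K27ac → **primed_enhancer**;
* else **other**.

Promoter activity is keyed on H3K27ac; if a dataset provides H3K4me3, the
`active_mark` / `enhancer_marks` fields accept any mark names. Nearest-gene
assignment measures |TSS − region midpoint| with ties broken by lower TSS
coordinate then lexicographic gene id, making assignment deterministic; a
gene-body distance variant was considered and rejected as less standard for
TSS tables.

Adipogenic enhancers are active enhancers overlapped by C/EBPα, C/EBPβ, or
PPARγ peaks, partitioned into C/EBP⁺PPARγ⁻ / C/EBP⁻PPARγ⁺ / C/EBP⁺PPARγ⁺
(C/EBP = α ∪ β; mutually exclusive and exhaustive). Adipogenic promoters
are, for each adipogenic enhancer, the nearest promoter by midpoint distance
(ties to the lower coordinate), deduplicated.

## Co-localization statistics

Venn partitions count universe elements when a universe is given (e.g.
active enhancers), else merged-union elements of the input sets — each
counting unit falls in exactly one cell. Profiles and heatmaps bin
fragment-midpoint density around region midpoints, normalized to
tags-per-million per kb of bin width so they are depth-invariant; defaults
are ±2,000 bp in 100 bins (40 bp/bin). These window/normalization choices
are this package's, not published values. Top-N selection (default 3,000)
ranks by island score with coordinate tie-breaks; it exists as the hand-off
to external motif tools, which are out of scope.

## Expression classification

fold(D2/D0) = (D2 + ε)/(D0 + ε) with pseudocount ε = 0.1 guarding
zero-expression genes; cutoffs (default 2.5) are inclusive on both sides.
The classifier is scale-invariant when ε is scaled with the data. Dependency
among up-regulated genes has two operationalizations, both shipped:

* **ratio** (default): (GFP-D2 + ε)/(Cre-D2 + ε) ≥ cutoff — knockout
  expression at D2 sits at least cutoff-fold below control;
* **induction**: (Cre-D2 + ε)/(Cre-D0 + ε) < cutoff — the knockout's own
  induction fails the regulation cutoff.

Result tables record the mode used. An expression floor
(`expressed_gene_filter`) restricts the gene universe; the default floor is
0 (all genes) since expression units are dataset-dependent.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, at
desk scale, with one global seed spawning independent sub-streams (layout,
marks, each tag library, expression):

* genome 2 × 5 Mb; 500 genes with uniformly placed TSS;
* 400 planted, mutually disjoint elements in a 40/30/20/10
  active-enhancer / primed-enhancer / active-promoter / silent-promoter mix;
  promoter elements are centered on a TSS, enhancer elements are kept
  > 3.5 kb from every TSS so classification is unambiguous; marks are
  emitted as clean peaks equal to the element intervals (the classifier
  consumes called mark peaks, and clean peaks keep recovery tests
  deterministic), with optional boundary jitter/dropout for robustness
  tests;
* 60% of active enhancers carry C/EBP (split over α/β with some overlap)
  and 40% carry PPARγ — echoing the reported majority co-occupancy of the
  reader with C/EBPs during adipogenesis;
* 200 true islands (1–3 kb wide) at 20-fold enrichment over a 5,000 tags/Mb
  Poisson background, enriched in both control replicates and absent from
  the knockout; 50 artifact islands enriched equally in all three libraries;
  half of the true islands are centered on planted active enhancers,
  mirroring the concentration of reader binding on active enhancers;
* expression in the study's proportions at 500-gene scale: 25 up- and 32
  down-regulated genes (planted folds 4–10, safely beyond the 2.5 cutoff so
  boundary behavior is tested separately with hand-built tables), 11 of the
  up genes knockout-dependent (KO reduction ≥ 4-fold); multiplicative
  lognormal noise with σ = 0.2 by default (σ = 0 for exact-recovery tests).

What passing these tests shows: the caller, filter, classifier, and
dependency logic implement their contracts exactly and recover planted
structure under realistic Poisson sampling noise. What it does not show:
robustness to mappability and GC bias, fragment-size mis-specification,
broad-domain marks with diffuse boundaries, replicate batch effects, or
RNA-seq dispersion structure — none of which the generator models.

## Problem sizes

Default test and acceptance runs use the 10 Mb synthetic genome
(~90k tags/library), 50 toy genomes of ≤ 100 kb for brute-force oracle
equivalence, 100 (tests) / 50 (acceptance script) 1 Mb replicates for null
FDR calibration, and 10 (tests) / 5 (script) seeds for island-recovery
averages — sizes chosen so the whole suite runs in well under a minute per
property while keeping Monte-Carlo error far from the asserted margins.

## Numerical choices and degenerate inputs

* Percentages are rounded half-up (6129/8309 → 73.8), so printed report
  percentages recompute exactly from adjacent counts.
* Poisson/binomial tails come from scipy; BH adjustment from statsmodels.
* Monte-Carlo calibration with zero simulated background islands returns
  threshold 0 with a warning; with fewer islands than E·n_sims it returns
  the maximum observed score (conservative) with a warning.
* Empty tag libraries yield no islands; empty interval sets are valid
  everywhere except where a denominator would vanish (overlap percentage,
  genomic distribution, recall), which raise.
* Ties are always broken by coordinate (then gene id) so every output is
  deterministic and order-invariant; reruns with fixed seeds are
  byte-identical.

## Known limitations

* The Monte-Carlo E-value calibration adds O(n_sims) simulated passes per
  caller invocation; for repeated calls on the same genome/depth the
  threshold can be computed once and passed explicitly.
* The differential filter tests each island independently; it does not
  model spatial correlation of background along the genome.
* The classifier takes mark peaks as given and does not call them from mark
  tag libraries.
* Genomes are haploid and single-assembly; no liftover, no BAM input (tag
  BED and chrom-sizes only).
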