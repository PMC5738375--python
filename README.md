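# enhancerstate

Analysis toolkit for mapping where an enhancer-binding chromatin reader sits
on the genome during cell differentiation, and which induced genes depend on
it. It implements, as a tested and reusable pipeline:

* **broad-island ChIP-seq peak calling** (SICER-style window/gap islands over
  a Poisson background, 50 bp windows and 50 bp gaps by default);
* **knockout-background differential filtering** — candidate islands are kept
  only when control enrichment significantly exceeds the knockout ChIP
  (one-sided binomial test, library-size normalized, Benjamini–Hochberg FDR
  < 10⁻³ by default), removing antibody off-target signal;
* **replicate intersection** into high-confidence binding regions;
* **regulatory-element classification** from histone-mark peaks
  (H3K4me1/2 ± H3K27ac; active/primed enhancer, active/silent promoter) and
  derivation of adipogenic enhancers (active enhancers bound by C/EBPα,
  C/EBPβ, or PPARγ) and their nearest promoters;
* **co-localization statistics** — Venn partitions over a region universe,
  average binding profiles and heatmap matrices around region centers, top-N
  region selection for external motif tools;
* **two-stage fold-change gene classification** — genes 2.5-fold up or down
  between D0 and D2 of differentiation, with up-regulated genes split into
  knockout-dependent and -independent at a second 2.5-fold cutoff;
* **a seeded synthetic-data generator** that plants enriched islands,
  artifact islands shared with the knockout, mark-defined element states, TF
  occupancy, and regulated/dependent genes — so every stage is testable
  end-to-end against known truth without any external download.

Intended users: computational biologists who want the individual statistical
steps of this style of enhancer analysis as composable, tested library
functions rather than a monolithic script.

## Model

Tags (5′ read starts) are shifted half a fragment toward 3′ and counted in
non-overlapping windows of *w* bp. With λ the expected background tags per
window (library size × *w* / effective genome length), a window with count
*k* is *eligible* when the Poisson upper tail P(X ≥ k; λ) falls below a
probability threshold (default 0.2). Eligible windows separated by at most
*g* bp of ineligible windows are joined into islands, scored

&nbsp;&nbsp;&nbsp;&nbsp;S = Σ over eligible windows −ln P(X = kᵢ; λ).

The genome-wide score threshold is calibrated by seeded Monte-Carlo
simulation of uniform background libraries so that the expected number of
background islands passing equals a target E-value (default 100).

For the knockout filter, an island with pooled control count *c* and
knockout count *k* is tested one-sided against Binomial(c + k, p₀) with
p₀ = N꜀/(N꜀+Nₖ); q-values are BH-adjusted across islands.

Gene calls use fold = (D2 + ε)/(D0 + ε) in the control genotype (ε = 0.1
pseudocount, cutoffs inclusive) and dependency = (GFP-D2 + ε)/(Cre-D2 + ε)
≥ 2.5 among up-regulated genes.

## Worked example

```python
from enhancerstate import (
    SimulationConfig, IslandParams, simulate_dataset, call_islands,
    differential_ko_filter, replicate_high_confidence, truth_compare,
    genomic_distribution, classify_regulation, classify_dependency,
)
from enhancerstate.islands import islands_to_interval_set

ds = simulate_dataset(SimulationConfig(seed=1))   # 2 x 5 Mb genome, planted truth
params = IslandParams(seed=1)
controls = [ds.libraries["control_rep1"], ds.libraries["control_rep2"]]

filtered = {}
for rep in ("control_rep1", "control_rep2"):
    calls = call_islands(ds.libraries[rep], params)
    kept = differential_ko_filter(calls, controls, ds.libraries["ko"],
                                  fdr=1e-3, params=params)
    print(f"{rep}: {len(calls)} islands, {len(kept)} survive the KO filter")
    filtered[rep] = kept

high_conf = replicate_high_confidence(
    islands_to_interval_set(filtered["control_rep1"], ds.genome),
    islands_to_interval_set(filtered["control_rep2"], ds.genome),
)
recall, precision = truth_compare(high_conf, ds.truth.true_islands)
print(f"high-confidence regions: {len(high_conf)} "
      f"(recall {recall:.2f}, precision {precision:.2f})")

for cls, (count, frac) in genomic_distribution(high_conf, ds.mark_sets, ds.tss).items():
    print(f"  {cls:16s} {count:4d}  {frac:.1%}")
```

prints

```
control_rep1: 263 islands, 209 survive the KO filter
control_rep2: 269 islands, 213 survive the KO filter
high-confidence regions: 200 (recall 1.00, precision 1.00)
  active_promoter     1  0.5%
  silent_promoter    26  13.0%
  active_enhancer   105  52.5%
  primed_enhancer     7  3.5%
  other              61  30.5%
```

All 200 planted true islands are recovered, every artifact island shared
with the knockout library is removed, and — because half of the planted true
islands sit on planted active enhancers — the class distribution of the
called regions is dominated by active enhancers. The two-stage expression
classifier on the same dataset calls 25 up / 32 down / 443 unchanged genes
and splits the up class into 11 dependent and 14 independent, matching the
planted labels exactly on noiseless expression.

The same stages are available from the shell:

```sh
enhancerstate simulate --seed 1 --out data/
enhancerstate callpeaks --treatment data/control_rep1.bed \
    --chrom-sizes data/chrom.sizes --window 50 --gap 50 --evalue 100 \
    --seed 1 --out islands.bed
enhancerstate kofilter --islands islands.bed \
    --control data/control_rep1.bed --control data/control_rep2.bed \
    --ko data/ko.bed --chrom-sizes data/chrom.sizes --fdr 1e-3 --out kept.bed
enhancerstate run --config pipeline.toml --out run/       # full pipeline
```

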