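"""Seeded generator of a complete toy dataset with planted ground truth.

Emulates the statistical structure the analysis assumes, at desk scale:

* uniform/Poisson background ChIP tags over a small multi-chromosome genome;
* planted enriched islands of configurable fold enrichment, present in two
  independent control replicates but absent from the knockout library;
* "artifact" islands (antibody off-target signal) enriched equally in
  control and knockout libraries;
* clean histone-mark peaks defining planted regulatory-element states
  (noisy-mark mode adds boundary jitter and dropout);
* TF peak sets covering a controlled fraction of active enhancers;
* a gene expression table with planted up/down-regulated genes and planted
  knockout-dependent induction.

One global seed drives independent per-stream sub-generators (layout, each
tag library, expression) so stages can be regenerated in isolation; the same
seed yields byte-identical output files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .elements import ConfigurationError
from .genomic import Genome, GenomicInterval, IntervalSet, TssTable, ValidationError, overlaps
from .io import write_bed, write_chrom_sizes, write_tss_table
from .islands import FORWARD, REVERSE, TagLibrary
from .expression import ExpressionTable

TRUTH_SCHEMA_VERSION = 1

DEFAULT_ELEMENT_MIX = {
    "active_enhancer": 0.4,
    "primed_enhancer": 0.3,
    "active_promoter": 0.2,
    "silent_promoter": 0.1,
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic dataset.

    Defaults give a 2 x 5 Mb genome with 500 genes, 200 true + 50 artifact
    islands at 20-fold enrichment over a 5000 tags/Mb background, a
    40/30/20/10 element mix, and gene-regulation counts in the study's
    proportions (5% up, 6.4% down; 43% of up genes knockout-dependent).
    """

    seed: int = 0
    chrom_lengths: tuple[int, ...] = (5_000_000, 5_000_000)
    n_genes: int = 500
    n_true_islands: int = 200
    n_artifact_islands: int = 50
    island_width_bp: tuple[int, int] = (1000, 3000)
    enrichment_fold: float = 20.0
    background_tags_per_mb: int = 5000
    n_elements: int = 400
    element_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ELEMENT_MIX))
    frac_ae_with_cebp: float = 0.6
    frac_ae_with_pparg: float = 0.4
    frac_islands_on_active_enhancers: float = 0.5
    n_up_genes: int = 25
    n_down_genes: int = 32
    n_dependent: int = 11
    noise_sigma: float = 0.2
    fragment_size: int = 250
    read_length: int = 50
    mark_jitter_bp: int = 0
    mark_dropout: float = 0.0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_true_islands, self.n_artifact_islands) < 0:
            raise ValidationError("counts must be >= 0")
        if abs(sum(self.element_mix.values()) - 1.0) > 1e-9:
            raise ValidationError("element_mix fractions must sum to 1")
        for frac in (self.frac_ae_with_cebp, self.frac_ae_with_pparg, self.mark_dropout):
            if not (0 <= frac <= 1):
                raise ValidationError("fractions must lie in [0, 1]")
        if self.n_up_genes + self.n_down_genes > self.n_genes:
            raise ValidationError("more regulated genes than genes")
        if self.n_dependent > self.n_up_genes:
            raise ValidationError("more dependent genes than up genes")
        if self.enrichment_fold < 1:
            raise ValidationError("enrichment_fold must be >= 1")

    @property
    def genome(self) -> Genome:
        return Genome(tuple((f"chr{i+1}", l) for i, l in enumerate(self.chrom_lengths)))


@dataclass
class SyntheticTruth:
    """Planted ground truth used by the test surface."""

    true_islands: IntervalSet
    artifact_islands: IntervalSet
    elements: pd.DataFrame  # chrom,start,end,element_class,CEBPA,CEBPB,PPARG
    gene_truth: pd.DataFrame  # gene_id,regulation,dependency


@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset; `write` emits it as plain-text files."""

    config: SimulationConfig
    genome: Genome
    tss: TssTable
    mark_sets: dict[str, IntervalSet]
    tf_sets: dict[str, IntervalSet]
    libraries: dict[str, TagLibrary]  # control_rep1, control_rep2, ko
    expression: ExpressionTable
    truth: SyntheticTruth

    def write(self, outdir: str | os.PathLike) -> dict[str, Path]:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        paths["chrom_sizes"] = out / "chrom.sizes"
        write_chrom_sizes(self.genome, paths["chrom_sizes"])
        paths["tss"] = out / "tss.tsv"
        write_tss_table(self.tss, paths["tss"])
        for name, iset in {**self.mark_sets, **self.tf_sets}.items():
            paths[name] = out / f"{name}.bed"
            write_bed(iset, paths[name])
        for name, lib in self.libraries.items():
            paths[name] = out / f"{name}.bed"
            _write_tag_bed(lib, paths[name], self.config.read_length)
        paths["expression"] = out / "expression.tsv"
        self.expression.write_tsv(paths["expression"])

        paths["truth_true_islands"] = out / "truth_true_islands.bed"
        write_bed(self.truth.true_islands, paths["truth_true_islands"])
        paths["truth_artifact_islands"] = out / "truth_artifact_islands.bed"
        write_bed(self.truth.artifact_islands, paths["truth_artifact_islands"])
        for name, df in (("truth_elements", self.truth.elements),
                         ("truth_genes", self.truth.gene_truth)):
            paths[name] = out / f"{name}.tsv"
            with open(paths[name], "w") as fh:
                fh.write(f"# truth-schema-version: {TRUTH_SCHEMA_VERSION}\n")
                df.to_csv(fh, sep="\t", index=False)
        return paths


def _write_tag_bed(lib: TagLibrary, path: Path, read_length: int) -> None:
    with open(path, "w") as fh:
        for chrom, (pos, strand) in sorted(lib.tags.items()):
            length = lib.genome.length(chrom)
            for p, s in zip(pos, strand):
                if s == FORWARD:
                    start, end, sym = p, min(p + read_length, length), "+"
                else:
                    start, end, sym = max(p + 1 - read_length, 0), p + 1, "-"
                fh.write(f"{chrom}\t{start}\t{end}\t.\t0\t{sym}\n")


# ---------------------------------------------------------------------------
# placement helpers


def _sample_chrom(rng: np.random.Generator, genome: Genome, n: int) -> np.ndarray:
    lengths = np.array([l for _, l in genome.chroms], dtype=float)
    return rng.choice(len(lengths), size=n, p=lengths / lengths.sum())


class _Layout:
    """Rejection-samples non-overlapping placements on a genome."""

    def __init__(self, genome: Genome, min_separation: int = 1000):
        self.genome = genome
        self.min_separation = min_separation
        self.placed: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.names}

    def free(self, chrom: str, start: int, end: int) -> bool:
        pad = self.min_separation
        return all(e + pad <= start or end + pad <= s for s, e in self.placed[chrom])

    def place(
        self,
        rng: np.random.Generator,
        width: int,
        margin: int,
        accept=None,
        max_tries: int = 2000,
    ) -> GenomicInterval:
        for _ in range(max_tries):
            ci = int(_sample_chrom(rng, self.genome, 1)[0])
            chrom, length = self.genome.chroms[ci]
            if length - margin - width <= margin:
                continue
            start = int(rng.integers(margin, length - margin - width))
            end = start + width
            if not self.free(chrom, start, end):
                continue
            if accept is not None and not accept(chrom, start, end):
                continue
            self.placed[chrom].append((start, end))
            return GenomicInterval(chrom, start, end)
        raise ConfigurationError(
            "infeasible placement: too many elements for the configured genome"
        )


# ---------------------------------------------------------------------------
# generation stages


def _generate_tss(rng: np.random.Generator, cfg: SimulationConfig) -> TssTable:
    genome = cfg.genome
    margin = 20_000
    seen: set[tuple[int, int]] = set()
    rows = []
    width = len(str(max(cfg.n_genes, 1)))
    for i in range(cfg.n_genes):
        while True:
            ci = int(_sample_chrom(rng, genome, 1)[0])
            chrom, length = genome.chroms[ci]
            pos = int(rng.integers(margin, length - margin))
            if (ci, pos) not in seen:
                seen.add((ci, pos))
                break
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((f"gene{i:0{width}d}", chrom, pos, strand))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])
    return TssTable(df, genome=genome)


def _generate_elements(
    rng: np.random.Generator, cfg: SimulationConfig, tss: TssTable, layout: _Layout
) -> pd.DataFrame:
    """Plant disjoint regulatory elements; promoter-class elements sit on a
    TSS, enhancer-class elements are kept distal (>3.5 kb from every TSS)."""
    counts = {cls: int(round(cfg.element_mix.get(cls, 0.0) * cfg.n_elements))
              for cls in DEFAULT_ELEMENT_MIX}
    # rounding drift goes to the largest class
    drift = cfg.n_elements - sum(counts.values())
    if drift:
        biggest = max(counts, key=lambda c: counts[c])
        counts[biggest] += drift

    tss_by_chrom = {c: grp["tss"].to_numpy() for c, grp in tss.records.groupby("chrom")}

    def distal(chrom: str, start: int, end: int) -> bool:
        sites = tss_by_chrom.get(chrom)
        mid = (start + end) // 2
        return sites is None or np.abs(sites - mid).min() > 3500

    n_promoter = counts["active_promoter"] + counts["silent_promoter"]
    if n_promoter > len(tss):
        raise ConfigurationError("more promoter elements than genes")
    candidate_genes = iter(rng.permutation(len(tss)))

    rows = []
    half = 500
    for cls in ("active_promoter", "silent_promoter"):
        placed = 0
        while placed < counts[cls]:
            try:
                gi = int(next(candidate_genes))
            except StopIteration:
                raise ConfigurationError(
                    "infeasible placement: not enough well-separated TSS for promoters"
                ) from None
            rec = tss.records.iloc[gi]
            chrom = str(rec["chrom"])
            start = max(int(rec["tss"]) - half, 0)
            end = min(int(rec["tss"]) + half, layout.genome.length(chrom))
            if not layout.free(chrom, start, end):
                continue  # this TSS collides with a placed element; try another
            layout.placed[chrom].append((start, end))
            rows.append((rec["chrom"], start, end, cls))
            placed += 1
    for cls in ("active_enhancer", "primed_enhancer"):
        for _ in range(counts[cls]):
            iv = layout.place(rng, width=1000, margin=10_000, accept=distal)
            rows.append((iv.chrom, iv.start, iv.end, cls))

    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "element_class"])
    is_ae = (df["element_class"] == "active_enhancer").to_numpy()
    cebp = is_ae & (rng.random(len(df)) < cfg.frac_ae_with_cebp)
    # split C/EBP occupancy over the two paralogs; some enhancers carry both
    which = rng.random(len(df))
    df["CEBPA"] = cebp & (which < 0.45)
    df["CEBPB"] = cebp & (which >= 0.25)
    df["PPARG"] = is_ae & (rng.random(len(df)) < cfg.frac_ae_with_pparg)
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def _mark_sets_from_elements(
    rng: np.random.Generator, cfg: SimulationConfig, elements: pd.DataFrame, genome: Genome
) -> tuple[dict[str, IntervalSet], dict[str, IntervalSet]]:
    def emit(mask: pd.Series) -> IntervalSet:
        ivs = []
        for _, row in elements[mask].iterrows():
            start, end = int(row["start"]), int(row["end"])
            if cfg.mark_dropout and rng.random() < cfg.mark_dropout:
                continue
            if cfg.mark_jitter_bp:
                start = max(0, start + int(rng.integers(-cfg.mark_jitter_bp, cfg.mark_jitter_bp + 1)))
                end = min(genome.length(str(row["chrom"])),
                          end + int(rng.integers(-cfg.mark_jitter_bp, cfg.mark_jitter_bp + 1)))
                if start >= end:
                    continue
            ivs.append(GenomicInterval(str(row["chrom"]), start, end))
        return IntervalSet(ivs, genome=genome)

    cls = elements["element_class"]
    enhancer = cls.isin(["active_enhancer", "primed_enhancer"])
    active = cls.isin(["active_enhancer", "active_promoter"])
    marks = {
        "H3K4me1": emit(enhancer),
        "H3K4me2": emit(enhancer),
        "H3K27ac": emit(active),
    }
    tfs = {name: emit(elements[name].astype(bool)) for name in ("CEBPA", "CEBPB", "PPARG")}
    return marks, tfs


def _place_islands(
    rng: np.random.Generator, cfg: SimulationConfig, elements: pd.DataFrame
) -> tuple[IntervalSet, IntervalSet]:
    """Plant mutually disjoint true and artifact islands.

    A configurable fraction of true islands is centered on planted active
    enhancers (binding concentrates on active enhancers in the system being
    emulated); the rest, and all artifact islands, land anywhere. Islands may
    overlap elements but never one another.
    """
    genome = cfg.genome
    layout = _Layout(genome)  # separate from the element layout on purpose
    lo, hi = cfg.island_width_bp
    true_ivs: list[GenomicInterval] = []

    ae = elements[elements["element_class"] == "active_enhancer"]
    n_on_ae = min(int(round(cfg.frac_islands_on_active_enhancers * cfg.n_true_islands)), len(ae))
    candidates = iter(rng.permutation(len(ae)))
    while len(true_ivs) < n_on_ae:
        try:
            row = ae.iloc[int(next(candidates))]
        except StopIteration:
            break  # too few well-separated enhancers; fall through to random
        width = int(rng.integers(lo, hi + 1))
        mid = (int(row["start"]) + int(row["end"])) // 2
        chrom = str(row["chrom"])
        start = max(mid - width // 2, 0)
        end = min(start + width, genome.length(chrom))
        if not layout.free(chrom, start, end):
            continue
        layout.placed[chrom].append((start, end))
        true_ivs.append(GenomicInterval(chrom, start, end))

    artifact_ivs: list[GenomicInterval] = []
    for bucket, n in ((true_ivs, cfg.n_true_islands), (artifact_ivs, cfg.n_artifact_islands)):
        while len(bucket) < n:
            width = int(rng.integers(lo, hi + 1))
            bucket.append(layout.place(rng, width=width, margin=5000))
    return IntervalSet(true_ivs, genome=genome), IntervalSet(artifact_ivs, genome=genome)


def _draw_tags(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    enriched: list[IntervalSet],
) -> TagLibrary:
    """One tag library: uniform Poisson background plus extra tags in the
    given enriched interval sets, so an enriched island's expected total is
    enrichment_fold x background rate x width."""
    genome = cfg.genome
    rate = cfg.background_tags_per_mb / 1e6  # tags per bp
    shift = cfg.fragment_size // 2
    midpoints: dict[str, list[np.ndarray]] = {c: [] for c in genome.names}
    for chrom, length in genome.chroms:
        n_bg = rng.poisson(rate * length)
        midpoints[chrom].append(rng.integers(0, length, size=n_bg))
    for iset in enriched:
        for iv in iset:
            n_extra = rng.poisson((cfg.enrichment_fold - 1.0) * rate * iv.width)
            midpoints[iv.chrom].append(rng.integers(iv.start, iv.end, size=n_extra))
    tags = {}
    for chrom, length in genome.chroms:
        mids = np.concatenate(midpoints[chrom]) if midpoints[chrom] else np.empty(0, dtype=np.int64)
        strand = np.where(rng.random(mids.size) < 0.5, FORWARD, REVERSE).astype(np.int8)
        pos = np.clip(mids - shift * strand, 0, length - 1)  # 5' read start
        order = np.argsort(pos, kind="stable")
        tags[chrom] = (pos[order].astype(np.int64), strand[order])
    return TagLibrary(genome, tags, fragment_size=cfg.fragment_size)


def _generate_expression(
    rng: np.random.Generator, cfg: SimulationConfig, tss: TssTable
) -> tuple[ExpressionTable, pd.DataFrame]:
    genes = tss.records["gene_id"].to_list()
    n = len(genes)
    order = rng.permutation(n)
    up = set(order[: cfg.n_up_genes])
    down = set(order[cfg.n_up_genes : cfg.n_up_genes + cfg.n_down_genes])
    dependent = set(order[: cfg.n_dependent])  # a subset of the up genes

    baseline = rng.uniform(5.0, 50.0, size=n)
    up_fold = rng.uniform(4.0, 10.0, size=n)  # safely above the 2.5 cutoff
    dep_loss = rng.uniform(4.0, 8.0, size=n)  # KO reduction for dependent genes

    gfp_d0 = baseline.copy()
    gfp_d2 = baseline.copy()
    regulation = np.full(n, "unchanged", dtype=object)
    dependency = np.full(n, "not_applicable", dtype=object)
    for i in range(n):
        if i in up:
            gfp_d2[i] = baseline[i] * up_fold[i]
            regulation[i] = "up"
            dependency[i] = "dependent" if i in dependent else "independent"
        elif i in down:
            gfp_d2[i] = baseline[i] / up_fold[i]
            regulation[i] = "down"
    cre_d0 = baseline.copy()
    cre_d2 = gfp_d2.copy()
    for i in dependent:
        cre_d2[i] = gfp_d2[i] / dep_loss[i]

    values = pd.DataFrame(
        {"GFP_D0": gfp_d0, "GFP_D2": gfp_d2, "Cre_D0": cre_d0, "Cre_D2": cre_d2},
        index=pd.Index(genes, name="gene_id"),
    )
    if cfg.noise_sigma > 0:
        noise = np.exp(rng.normal(0.0, cfg.noise_sigma, size=values.shape))
        values = values * noise
    truth = pd.DataFrame(
        {"gene_id": genes, "regulation": regulation, "dependency": dependency}
    )
    return ExpressionTable(values.round(4)), truth


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate the full synthetic dataset; deterministic given cfg.seed."""
    streams = np.random.SeedSequence(cfg.seed).spawn(6)
    rng_layout = np.random.default_rng(streams[0])
    rng_marks = np.random.default_rng(streams[1])
    rng_expr = np.random.default_rng(streams[2])
    lib_rngs = {name: np.random.default_rng(s)
                for name, s in zip(("control_rep1", "control_rep2", "ko"), streams[3:6])}

    genome = cfg.genome
    tss = _generate_tss(rng_layout, cfg)
    layout = _Layout(genome)
    elements = _generate_elements(rng_layout, cfg, tss, layout)
    true_islands, artifact_islands = _place_islands(rng_layout, cfg, elements)
    marks, tfs = _mark_sets_from_elements(rng_marks, cfg, elements, genome)

    libraries = {
        "control_rep1": _draw_tags(lib_rngs["control_rep1"], cfg, [true_islands, artifact_islands]),
        "control_rep2": _draw_tags(lib_rngs["control_rep2"], cfg, [true_islands, artifact_islands]),
        "ko": _draw_tags(lib_rngs["ko"], cfg, [artifact_islands]),
    }
    expression, gene_truth = _generate_expression(rng_expr, cfg, tss)

    truth = SyntheticTruth(
        true_islands=true_islands,
        artifact_islands=artifact_islands,
        elements=elements,
        gene_truth=gene_truth,
    )
    return SyntheticDataset(
        config=cfg,
        genome=genome,
        tss=tss,
        mark_sets=marks,
        tf_sets=tfs,
        libraries=libraries,
        expression=expression,
        truth=truth,
    )


def truth_compare(
    predicted: IntervalSet, truth: IntervalSet, min_bp: int = 1
) -> tuple[float, float]:
    """(recall, precision) of predicted regions against planted truth.

    A truth interval is recalled when >= min_bp bases are shared with any
    prediction; a prediction is a true positive when it matches any truth
    interval. Empty truth raises; empty predictions give (0, 0).
    """
    if len(truth) == 0:
        raise ValidationError("recall undefined for empty truth")
    if len(predicted) == 0:
        return 0.0, 0.0
    recall = float(overlaps(truth, predicted, min_bp=min_bp).mean())
    precision = float(overlaps(predicted, truth, min_bp=min_bp).mean())
    return recall, precision
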