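"""SICER-style broad-island calling with knockout-background filtering.

The caller partitions each chromosome into non-overlapping windows (default
50 bp), marks windows whose shifted-tag count clears a Poisson eligibility
threshold, joins eligible windows separated by at most a bounded gap (default
50 bp) into islands, and scores each island as the summed -ln Poisson
probability of its eligible windows. The genome-wide score threshold is
calibrated by seeded Monte-Carlo simulation of uniform background libraries
so that the expected number of background islands passing equals `evalue`.

Candidate islands are then filtered against a knockout (KO) ChIP library:
an island is kept only when its pooled-control tag count is significantly
higher than expected from the KO library under a one-sided binomial test
(library-size normalized), Benjamini-Hochberg adjusted across islands. This
removes antibody off-target "artifact" islands, which appear equally in
control and KO chromatin. High-confidence regions are finally the overlap of
two biological replicates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomic import Genome, GenomicInterval, IntervalSet, ValidationError, merge_intervals
from .io import iter_bed_records

logger = logging.getLogger(__name__)

FORWARD, REVERSE = 1, -1


@dataclass
class TagLibrary:
    """A ChIP-seq tag library: per-chromosome 5' read-start positions.

    `tags` maps chromosome -> (positions, strands) where strands are +1/-1.
    `fragment_size` is the sonicated-fragment length in bp (default 250, the
    midpoint of a 200-500 bp sonication range); each tag is shifted by half a
    fragment toward its 3' end to approximate the fragment midpoint.
    """

    genome: Genome
    tags: dict[str, tuple[np.ndarray, np.ndarray]]
    fragment_size: int = 250

    def __post_init__(self) -> None:
        for chrom, (pos, strand) in self.tags.items():
            if chrom not in self.genome:
                raise ValidationError(f"tags on unknown chromosome {chrom}")
            if pos.size and (pos.min() < 0 or pos.max() >= self.genome.length(chrom)):
                raise ValidationError(f"tag position outside {chrom} bounds")
            if pos.shape != strand.shape:
                raise ValidationError("positions and strands differ in length")

    @property
    def library_size(self) -> int:
        return int(sum(pos.size for pos, _ in self.tags.values()))

    def remove_redundant(self, threshold: int = 1) -> "TagLibrary":
        """Keep at most `threshold` tags at any identical (position, strand)."""
        if threshold < 1:
            raise ValidationError("redundancy threshold must be >= 1")
        out = {}
        for chrom, (pos, strand) in self.tags.items():
            order = np.lexsort((strand, pos))
            p, s = pos[order], strand[order]
            if p.size == 0:
                out[chrom] = (p, s)
                continue
            new_run = np.ones(p.size, dtype=bool)
            new_run[1:] = (p[1:] != p[:-1]) | (s[1:] != s[:-1])
            run_id = np.cumsum(new_run) - 1
            run_starts = np.flatnonzero(new_run)
            rank_in_run = np.arange(p.size) - run_starts[run_id]
            keep = rank_in_run < threshold
            out[chrom] = (p[keep], s[keep])
        return TagLibrary(self.genome, out, self.fragment_size)

    def shifted_positions(self) -> dict[str, np.ndarray]:
        """Fragment-midpoint positions: 5' start shifted fragment_size/2
        toward 3', clipped to chromosome bounds, sorted."""
        shift = self.fragment_size // 2
        out = {}
        for chrom, (pos, strand) in self.tags.items():
            shifted = pos + shift * strand
            shifted = np.clip(shifted, 0, self.genome.length(chrom) - 1)
            out[chrom] = np.sort(shifted)
        return out


def read_tag_bed(
    path, genome: Genome, fragment_size: int = 250
) -> TagLibrary:
    """Load a mapped-read BED as a tag library (one record per read).

    The tag position is the read's 5' end: `start` for + strand, `end - 1`
    for - strand. Unstranded records are treated as forward reads.
    """
    per_chrom_pos: dict[str, list[int]] = {}
    per_chrom_strand: dict[str, list[int]] = {}
    for lineno, chrom, start, end, strand in iter_bed_records(path):
        if chrom not in genome:
            raise ValidationError(f"{path}:{lineno}: unknown chromosome {chrom}")
        if strand == "-":
            pos, s = end - 1, REVERSE
        else:
            pos, s = start, FORWARD
        per_chrom_pos.setdefault(chrom, []).append(pos)
        per_chrom_strand.setdefault(chrom, []).append(s)
    tags = {
        c: (np.asarray(per_chrom_pos[c], dtype=np.int64),
            np.asarray(per_chrom_strand[c], dtype=np.int8))
        for c in per_chrom_pos
    }
    return TagLibrary(genome, tags, fragment_size)


@dataclass
class IslandParams:
    """Tunable parameters of the island caller.

    window_bp/gap_bp default to 50/50; window_p is the Poisson upper-tail
    probability bounding an "eligible" window (0.2); evalue is the expected
    number of background islands passing the score threshold genome-wide.
    """

    window_bp: int = 50
    gap_bp: int = 50
    window_p: float = 0.2
    evalue: float = 100.0
    redundancy_threshold: int = 1
    effective_genome_fraction: float = 0.8
    n_calibration_sims: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValidationError("window_bp must be positive")
        if self.gap_bp < 0 or self.gap_bp % self.window_bp != 0:
            raise ValidationError("gap_bp must be a non-negative multiple of window_bp")
        if not (0 < self.window_p < 1):
            raise ValidationError("window_p must be in (0, 1)")
        if self.evalue <= 0:
            raise ValidationError("evalue must be positive")
        if not (0 < self.effective_genome_fraction <= 1):
            raise ValidationError("effective_genome_fraction must be in (0, 1]")

    @property
    def gap_windows(self) -> int:
        return self.gap_bp // self.window_bp


@dataclass
class IslandCall:
    """A scored enriched region with optional differential-test annotations."""

    interval: GenomicInterval
    score: float
    counts: dict[str, int] = field(default_factory=dict)
    diff_p: float | None = None
    diff_q: float | None = None

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValidationError("island score must be >= 0")


def shift_and_count_windows(lib: TagLibrary, params: IslandParams) -> dict[str, np.ndarray]:
    """Per-chromosome window tag counts after redundancy filtering and
    fragment-midpoint shifting. Counts sum to the retained tag count."""
    retained = lib.remove_redundant(params.redundancy_threshold)
    all_shifted = retained.shifted_positions()
    counts = {}
    for chrom, length in retained.genome.chroms:
        n_windows = -(-length // params.window_bp)
        shifted = all_shifted.get(chrom)
        if shifted is None:
            counts[chrom] = np.zeros(n_windows, dtype=np.int64)
        else:
            counts[chrom] = np.bincount(shifted // params.window_bp, minlength=n_windows)
    return counts


def background_lambda(n_tags: int, genome: Genome, params: IslandParams) -> float:
    """Expected background tags per window, over the effective genome."""
    effective = genome.total_length * params.effective_genome_fraction
    return n_tags * params.window_bp / effective


def eligible_threshold(lambda_bg: float, window_p: float) -> int:
    """Smallest integer l0 >= 1 with Poisson upper tail P(X >= l0) < window_p."""
    if lambda_bg <= 0:
        raise ValidationError("lambda_bg must be positive")
    l0 = 1
    while stats.poisson.sf(l0 - 1, lambda_bg) >= window_p:
        l0 += 1
    return l0


def find_islands(
    window_counts: np.ndarray, l0: int, gap_windows: int
) -> list[tuple[int, int]]:
    """Maximal runs of eligible windows (count >= l0) where consecutive
    eligible windows are separated by <= gap_windows ineligible ones.

    Returns (first, last) eligible-window indices, inclusive, per island.
    """
    eligible = np.flatnonzero(np.asarray(window_counts) >= l0)
    if eligible.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(eligible) > gap_windows + 1) + 1
    return [(int(g[0]), int(g[-1])) for g in np.split(eligible, breaks)]


def score_island(
    island: tuple[int, int], window_counts: np.ndarray, lambda_bg: float, l0: int
) -> float:
    """Aggregate island score: sum of -ln P(X = count; lambda) over the
    island's eligible windows."""
    first, last = island
    seg = np.asarray(window_counts[first : last + 1])
    elig = seg[seg >= l0]
    if elig.size == 0:
        raise ValidationError("island contains no eligible window")
    return float(np.sum(-stats.poisson.logpmf(elig, lambda_bg)))


def _islands_and_scores(
    counts: np.ndarray, l0: int, lambda_bg: float, gap_windows: int
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Vectorized find + score for one chromosome's window counts."""
    eligible = np.flatnonzero(counts >= l0)
    if eligible.size == 0:
        return [], np.empty(0)
    breaks = np.flatnonzero(np.diff(eligible) > gap_windows + 1) + 1
    groups = np.split(eligible, breaks)
    logp = -stats.poisson.logpmf(counts[eligible], lambda_bg)
    seg_starts = np.concatenate(([0], breaks))
    scores = np.add.reduceat(logp, seg_starts)
    return [(int(g[0]), int(g[-1])) for g in groups], scores


def _simulate_uniform_counts(
    genome: Genome, n_tags: int, window_bp: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    lengths = np.array([l for _, l in genome.chroms], dtype=np.int64)
    per_chrom = rng.multinomial(n_tags, lengths / lengths.sum())
    out = {}
    for (chrom, length), n in zip(genome.chroms, per_chrom):
        n_windows = -(-length // window_bp)
        pos = rng.integers(0, length, size=int(n))
        out[chrom] = np.bincount(pos // window_bp, minlength=n_windows)
    return out


def calibrate_score_threshold(
    genome: Genome, n_tags: int, params: IslandParams
) -> float:
    """Monte-Carlo island-score threshold.

    Simulates `n_calibration_sims` uniform-random libraries of `n_tags`,
    calls and scores islands, and returns the score s* such that the mean
    number of background islands with score >= s* equals `evalue`.
    Deterministic given params.seed.
    """
    if math.isinf(params.evalue):
        return 0.0
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0x5109]))
    lam = background_lambda(n_tags, genome, params)
    l0 = eligible_threshold(lam, params.window_p)
    pooled: list[np.ndarray] = []
    for _ in range(max(20, params.n_calibration_sims)):
        counts = _simulate_uniform_counts(genome, n_tags, params.window_bp, rng)
        for arr in counts.values():
            _, scores = _islands_and_scores(arr, l0, lam, params.gap_windows)
            if scores.size:
                pooled.append(scores)
    n_sims = max(20, params.n_calibration_sims)
    scores_desc = np.sort(np.concatenate(pooled))[::-1] if pooled else np.empty(0)
    k = int(round(params.evalue * n_sims))
    if scores_desc.size == 0:
        logger.warning("no background islands simulated; score threshold set to 0")
        return 0.0
    if k == 0:
        return float(scores_desc[0]) + 1.0
    if scores_desc.size < k:
        logger.warning(
            "only %d background islands over %d sims (< evalue*n_sims = %d); "
            "returning maximum observed score",
            scores_desc.size, n_sims, k,
        )
        return float(scores_desc[0])
    return float(scores_desc[k - 1])


def call_islands(
    lib: TagLibrary,
    params: IslandParams,
    score_threshold: float | None = None,
) -> list[IslandCall]:
    """Full island-calling pipeline on one library.

    Redundancy-filters, shifts, windows, finds and scores islands, and keeps
    those with score >= the (calibrated or explicitly given) threshold.
    Returned calls are sorted by coordinate; intervals lie on the window grid
    clipped to chromosome ends.
    """
    retained = lib.remove_redundant(params.redundancy_threshold)
    n_tags = retained.library_size
    if n_tags == 0:
        return []
    lam = background_lambda(n_tags, lib.genome, params)
    l0 = eligible_threshold(lam, params.window_p)
    counts = shift_and_count_windows(lib, params)
    if score_threshold is None:
        score_threshold = calibrate_score_threshold(lib.genome, n_tags, params)
    calls = []
    for chrom, length in lib.genome.chroms:
        islands, scores = _islands_and_scores(counts[chrom], l0, lam, params.gap_windows)
        for (first, last), score in zip(islands, scores):
            if score < score_threshold:
                continue
            start = first * params.window_bp
            end = min((last + 1) * params.window_bp, length)
            calls.append(IslandCall(GenomicInterval(chrom, start, end), float(score)))
    calls.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    return calls


def count_tags_in_intervals(lib: TagLibrary, intervals, params: IslandParams) -> np.ndarray:
    """Shifted, redundancy-filtered tag counts within each interval."""
    retained = lib.remove_redundant(params.redundancy_threshold)
    shifted = retained.shifted_positions()
    counts = np.zeros(len(intervals), dtype=np.int64)
    for i, iv in enumerate(intervals):
        pos = shifted.get(iv.chrom)
        if pos is None:
            continue
        counts[i] = np.searchsorted(pos, iv.end) - np.searchsorted(pos, iv.start)
    return counts


def differential_ko_filter(
    islands: list[IslandCall],
    control_libs: list[TagLibrary],
    ko_lib: TagLibrary,
    fdr: float = 1e-3,
    params: IslandParams | None = None,
) -> list[IslandCall]:
    """Keep islands whose control enrichment significantly exceeds KO.

    Per island, pooled control count c and KO count k are compared by a
    one-sided binomial test of c successes in c+k trials against
    p0 = Nc/(Nc+Nk) (retained library sizes); p-values are BH-adjusted across
    all islands and islands with q < fdr are kept. Islands with zero total
    count are dropped with a log notice. Returned islands carry counts,
    diff_p and diff_q.
    """
    if not (0 < fdr < 1):
        raise ValidationError("fdr must be in (0, 1)")
    params = params or IslandParams()
    if not islands:
        return []
    ivs = [isl.interval for isl in islands]
    control_counts = sum(count_tags_in_intervals(lib, ivs, params) for lib in control_libs)
    ko_counts = count_tags_in_intervals(ko_lib, ivs, params)
    n_control = sum(lib.remove_redundant(params.redundancy_threshold).library_size
                    for lib in control_libs)
    n_ko = ko_lib.remove_redundant(params.redundancy_threshold).library_size
    p0 = n_control / (n_control + n_ko)

    total = control_counts + ko_counts
    nonzero = total > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("dropping %d islands with zero total tag count", n_dropped)
    pvals = stats.binom.sf(control_counts[nonzero] - 1, total[nonzero], p0)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")

    kept = []
    idx = np.flatnonzero(nonzero)
    for j, i in enumerate(idx):
        isl = islands[i]
        isl.counts = {"control": int(control_counts[i]), "ko": int(ko_counts[i])}
        isl.diff_p = float(pvals[j])
        isl.diff_q = float(qvals[j])
        if isl.diff_q < fdr:
            kept.append(isl)
    return kept


def islands_to_interval_set(islands: list[IslandCall], genome: Genome | None = None) -> IntervalSet:
    return IntervalSet([isl.interval for isl in islands], genome=genome)


def islands_to_frame(islands: list[IslandCall]) -> pd.DataFrame:
    """Tab-writable island table: interval, score, counts, p, q."""
    return pd.DataFrame(
        {
            "chrom": [i.interval.chrom for i in islands],
            "start": [i.interval.start for i in islands],
            "end": [i.interval.end for i in islands],
            "score": [i.score for i in islands],
            "control_count": [i.counts.get("control") for i in islands],
            "ko_count": [i.counts.get("ko") for i in islands],
            "diff_p": [i.diff_p for i in islands],
            "diff_q": [i.diff_q for i in islands],
        }
    )


def replicate_high_confidence(
    rep1: IntervalSet, rep2: IntervalSet, mode: str = "union"
) -> IntervalSet:
    """High-confidence regions: replicate-overlapping islands.

    For every rep1 island overlapping >= 1 rep2 island, emits either the
    merged union of the overlapping pair(s) (`mode="union"`, default —
    preserves full island extent) or the shared footprint
    (`mode="intersection"`). Output is merged and sorted.
    """
    if mode not in ("union", "intersection"):
        raise ValidationError(f"unknown replicate-intersection mode {mode!r}")
    out = []
    by_chrom2 = rep2.by_chrom()
    for iv in rep1:
        if iv.chrom not in by_chrom2:
            continue
        starts2, ends2 = by_chrom2[iv.chrom]
        hit = (starts2 < iv.end) & (ends2 > iv.start)
        if not hit.any():
            continue
        if mode == "union":
            out.append(
                GenomicInterval(
                    iv.chrom,
                    min(iv.start, int(starts2[hit].min())),
                    max(iv.end, int(ends2[hit].max())),
                )
            )
        else:
            for s2, e2 in zip(starts2[hit], ends2[hit]):
                out.append(GenomicInterval(iv.chrom, max(iv.start, int(s2)), min(iv.end, int(e2))))
    return merge_intervals(IntervalSet(out, genome=rep1.genome))
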