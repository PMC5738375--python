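"""Venn partitions, average binding profiles, heatmap matrices, top-N regions.

These are the quantitative summaries behind co-localization figures: how TF
and cofactor peak sets partition over a universe of elements, what the mean
tag-density profile looks like around region centers, and the top-scoring
regions handed to external motif tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .genomic import GenomicInterval, IntervalSet, ValidationError, merge_intervals, overlaps
from .islands import IslandCall, TagLibrary

logger = logging.getLogger(__name__)


@dataclass
class VennPartition:
    """Counts per non-empty subset cell of 2-3 named interval sets.

    `cells` maps a frozenset of set names to the number of counting-unit
    regions overlapped by exactly those sets. Each counted region falls in
    exactly one cell, so cells sum to the universe size.
    """

    set_names: tuple[str, ...]
    cells: dict[frozenset, int]

    @property
    def total(self) -> int:
        return sum(self.cells.values())

    def cell(self, *names: str) -> int:
        return self.cells.get(frozenset(names), 0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in range(1, len(self.set_names) + 1):
            for combo in combinations(self.set_names, r):
                rows.append(("+".join(combo), self.cells.get(frozenset(combo), 0)))
        return pd.DataFrame(rows, columns=["cell", "count"])


def venn_counts(
    sets: dict[str, IntervalSet], universe: IntervalSet | None = None
) -> VennPartition:
    """Partition counts for 2-3 named peak sets.

    Counting units are universe elements when a universe is given (membership
    = >=1 bp overlap), else the merged-union elements of all input sets.
    Units overlapping none of the sets are not counted (they have no cell).
    """
    if not (2 <= len(sets) <= 3):
        raise ValidationError("venn_counts supports 2 or 3 sets")
    names = tuple(sets)
    if universe is None:
        pooled = [iv for s in sets.values() for iv in s]
        genome = next(iter(sets.values())).genome
        units = merge_intervals(IntervalSet(pooled, genome=genome))
    else:
        units = universe
    flags = {name: overlaps(units, s) for name, s in sets.items()}
    cells: dict[frozenset, int] = {}
    for i in range(len(units)):
        members = frozenset(n for n in names if flags[n][i])
        if members:
            cells[members] = cells.get(members, 0) + 1
    return VennPartition(names, cells)


@dataclass
class ProfileMatrix:
    """Per-region binned tag density around region centers.

    values is regions x bins, in tags-per-million per kb of bin width;
    flank_bp is the half-window around each region midpoint, so bin width is
    2*flank_bp/bins exactly.
    """

    regions: list[GenomicInterval]
    bins: int
    flank_bp: int
    values: np.ndarray
    included: np.ndarray  # False for regions clipped at a chromosome end

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.regions), self.bins):
            raise ValidationError("profile matrix dimensions mismatch")
        if (2 * self.flank_bp) % self.bins != 0:
            raise ValidationError("bins must divide 2*flank_bp")

    @property
    def bin_width(self) -> int:
        return 2 * self.flank_bp // self.bins

    def column_means(self) -> np.ndarray:
        """Mean profile over the non-clipped regions."""
        if not self.included.any():
            return np.full(self.bins, np.nan)
        return self.values[self.included].mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        offsets = -self.flank_bp + self.bin_width * (np.arange(self.bins) + 0.5)
        return pd.DataFrame(self.values, columns=[f"{o:+.0f}" for o in offsets])


def _profile_values(
    lib: TagLibrary, centers: IntervalSet, flank_bp: int, bins: int
) -> tuple[np.ndarray, np.ndarray]:
    if (2 * flank_bp) % bins != 0:
        raise ValidationError("bins must divide 2*flank_bp")
    bin_width = 2 * flank_bp // bins
    shifted = lib.shifted_positions()
    n_tags = lib.library_size
    # density in tags-per-million per kb of bin width
    norm = (1e6 / n_tags) * (1000.0 / bin_width) if n_tags else 0.0
    values = np.zeros((len(centers), bins))
    included = np.ones(len(centers), dtype=bool)
    for i, iv in enumerate(centers):
        mid = iv.midpoint
        lo, hi = mid - flank_bp, mid + flank_bp
        if lo < 0 or hi > lib.genome.length(iv.chrom):
            logger.warning(
                "region %s:%d-%d flank exceeds chromosome bounds; clipped and "
                "excluded from means", iv.chrom, iv.start, iv.end,
            )
            included[i] = False
            lo_c, hi_c = max(lo, 0), min(hi, lib.genome.length(iv.chrom))
        else:
            lo_c, hi_c = lo, hi
        pos = shifted.get(iv.chrom)
        if pos is None:
            continue
        sel = pos[np.searchsorted(pos, lo_c) : np.searchsorted(pos, hi_c)]
        if sel.size:
            idx = (sel - lo) // bin_width
            values[i] = np.bincount(idx.astype(np.int64), minlength=bins)[:bins] * norm
    return values, included


def average_profile(
    lib: TagLibrary, centers: IntervalSet, flank_bp: int = 2000, bins: int = 100
) -> tuple[ProfileMatrix, np.ndarray]:
    """Binned tag density around region midpoints plus the mean profile."""
    values, included = _profile_values(lib, centers, flank_bp, bins)
    matrix = ProfileMatrix(list(centers), bins, flank_bp, values, included)
    return matrix, matrix.column_means()


def heatmap_matrix(
    lib: TagLibrary,
    regions: IntervalSet,
    flank_bp: int = 2000,
    bins: int = 100,
    sort_by: str = "signal",
) -> ProfileMatrix:
    """Per-region profile matrix with deterministic row order.

    sort_by="signal" orders rows by total signal descending (ties by
    coordinate); sort_by="position" keeps coordinate order.
    """
    if sort_by not in ("signal", "position"):
        raise ValidationError(f"unknown sort_by {sort_by!r}")
    values, included = _profile_values(lib, regions, flank_bp, bins)
    region_list = list(regions)
    if sort_by == "signal":
        totals = values.sum(axis=1)
        order = sorted(
            range(len(region_list)),
            key=lambda i: (-totals[i], region_list[i].chrom, region_list[i].start),
        )
        values = values[order]
        included = included[order]
        region_list = [region_list[i] for i in order]
    return ProfileMatrix(region_list, bins, flank_bp, values, included)


def top_n_by_score(islands: list[IslandCall], n: int) -> IntervalSet:
    """The n highest-scoring islands (all if fewer); ties break by coordinate.

    This is the selection step feeding external motif-discovery tools.
    """
    if n <= 0:
        raise ValidationError("n must be positive")
    ranked = sorted(
        islands, key=lambda c: (-c.score, c.interval.chrom, c.interval.start, c.interval.end)
    )
    return IntervalSet([c.interval for c in ranked[:n]])
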