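"""Genome model, genomic intervals, and interval arithmetic.

All coordinates are 0-based, half-open (BED convention): an interval
``(chrom, start, end)`` covers bases ``start .. end-1``. "Overlap" means at
least one shared base unless a larger minimum is requested explicitly.
Strand is carried on intervals but ignored by overlap logic, since ChIP-seq
peak coordinates are unstranded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")


class ValidationError(ValueError):
    """An interval, set, or table violates a structural invariant."""


@dataclass(frozen=True)
class Genome:
    """An ordered collection of chromosomes with lengths in bp.

    Stands in for a real assembly (e.g. mm9/mm10); synthetic genomes used in
    testing are a few Mb.
    """

    chroms: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chroms]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names")
        for name, length in self.chroms:
            if length <= 0:
                raise ValidationError(f"chromosome {name} has non-positive length {length}")

    @classmethod
    def from_dict(cls, sizes: dict[str, int]) -> "Genome":
        return cls(tuple(sizes.items()))

    @property
    def sizes(self) -> dict[str, int]:
        return dict(self.chroms)

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chroms]

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chroms)

    def length(self, chrom: str) -> int:
        try:
            return self.sizes[chrom]
        except KeyError:
            raise ValidationError(f"unknown chromosome: {chrom}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval", min_bp: int = 1) -> bool:
        if self.chrom != other.chrom:
            return False
        shared = min(self.end, other.end) - max(self.start, other.start)
        return shared >= min_bp


class IntervalSet:
    """A sorted collection of genomic intervals on a shared genome.

    Internally column-oriented (numpy arrays per field) so merge / overlap /
    nearest queries vectorize; iteration yields :class:`GenomicInterval`.
    """

    def __init__(self, intervals: Iterable[GenomicInterval], genome: Genome | None = None):
        ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        if genome is not None:
            for iv in ivs:
                if iv.chrom not in genome:
                    raise ValidationError(f"interval on unknown chromosome {iv.chrom}")
                if iv.end > genome.length(iv.chrom):
                    raise ValidationError(
                        f"interval {iv.chrom}:{iv.start}-{iv.end} extends past "
                        f"chromosome end {genome.length(iv.chrom)}"
                    )
        self.genome = genome
        self._intervals: list[GenomicInterval] = ivs
        self.chrom = np.array([iv.chrom for iv in ivs], dtype=object)
        self.start = np.array([iv.start for iv in ivs], dtype=np.int64)
        self.end = np.array([iv.end for iv in ivs], dtype=np.int64)

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self._intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._intervals == other._intervals

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals)"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "strand": [iv.strand for iv in self._intervals],
            }
        )

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays, sorted by start."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for c in pd.unique(self.chrom):
            mask = self.chrom == c
            out[str(c)] = (self.start[mask], self.end[mask])
        return out


@dataclass
class TssTable:
    """Per-gene transcription start sites.

    records: DataFrame with columns gene_id (unique), chrom, tss (bp), strand.
    """

    records: pd.DataFrame
    genome: Genome | None = None

    REQUIRED = ("gene_id", "chrom", "tss", "strand")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValidationError(f"TSS table missing columns: {missing}")
        if self.records["gene_id"].duplicated().any():
            dup = self.records.loc[self.records["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValidationError(f"duplicate gene_id in TSS table: {dup}")
        if self.genome is not None:
            for _, row in self.records.iterrows():
                if row["chrom"] not in self.genome:
                    raise ValidationError(f"TSS on unknown chromosome {row['chrom']}")
                if not (0 <= row["tss"] < self.genome.length(row["chrom"])):
                    raise ValidationError(
                        f"TSS {row['gene_id']} at {row['tss']} outside {row['chrom']}"
                    )
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def chrom_index(self) -> dict[str, pd.DataFrame]:
        """Per-chromosome records sorted by (tss, gene_id) for nearest queries."""
        out = {}
        for c, grp in self.records.groupby("chrom", sort=False):
            out[str(c)] = grp.sort_values(["tss", "gene_id"]).reset_index(drop=True)
        return out


# ---------------------------------------------------------------------------
# Interval arithmetic


def merge_intervals(iset: IntervalSet) -> IntervalSet:
    """Minimal set of disjoint intervals covering the same bases.

    Touching-but-not-overlapping intervals (end == next start) are merged,
    matching per-base coverage semantics.
    """
    merged: list[GenomicInterval] = []
    for chrom, (starts, ends) in iset.by_chrom().items():
        cur_s, cur_e = None, None
        for s, e in zip(starts, ends):
            if cur_s is None:
                cur_s, cur_e = int(s), int(e)
            elif s <= cur_e:
                cur_e = max(cur_e, int(e))
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        if cur_s is not None:
            merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return IntervalSet(merged, genome=iset.genome)


def _check_same_genome(a: IntervalSet, b: IntervalSet) -> None:
    if a.genome is not None and b.genome is not None and a.genome != b.genome:
        raise ValidationError("interval sets are on different genomes")


def overlaps(a: IntervalSet, b: IntervalSet, min_bp: int = 1) -> np.ndarray:
    """Boolean flag per interval of `a`: does it share >= min_bp bases with any
    interval of `b`?"""
    _check_same_genome(a, b)
    if min_bp < 1:
        raise ValidationError("min_bp must be >= 1")
    flags = np.zeros(len(a), dtype=bool)
    if len(a) == 0 or len(b) == 0:
        return flags
    b_merged = merge_intervals(b) if min_bp == 1 else b
    b_by_chrom = b_merged.by_chrom()
    for chrom in pd.unique(a.chrom):
        chrom = str(chrom)
        amask = a.chrom == chrom
        if chrom not in b_by_chrom:
            continue
        bs, be = b_by_chrom[chrom]
        a_start = a.start[amask]
        a_end = a.end[amask]
        if min_bp == 1:
            # merged b intervals are disjoint and sorted: an a-interval overlaps
            # iff some b-start < a.end and the matching b-end > a.start
            idx = np.searchsorted(bs, a_end - 1, side="right")
            hit = np.zeros(len(a_start), dtype=bool)
            has_prev = idx > 0
            hit[has_prev] = be[idx[has_prev] - 1] > a_start[has_prev]
            flags[np.flatnonzero(amask)] = hit
        else:
            for i, (s, e) in zip(np.flatnonzero(amask), zip(a_start, a_end)):
                shared = np.minimum(e, be) - np.maximum(s, bs)
                flags[i] = bool((shared >= min_bp).any())
    return flags


def nearest_gene(region: GenomicInterval, tss: TssTable) -> tuple[str, int]:
    """Gene whose TSS is nearest the region midpoint.

    Distance is signed (TSS - midpoint). Ties broken by lower TSS coordinate,
    then lexicographic gene_id. Returns ("unassigned", 0) when the region's
    chromosome carries no TSS.
    """
    per_chrom = tss.chrom_index()
    if region.chrom not in per_chrom:
        return "unassigned", 0
    recs = per_chrom[region.chrom]
    mid = region.midpoint
    dist = np.abs(recs["tss"].to_numpy() - mid)
    # argmin on (|d|, tss, gene_id); recs already sorted by (tss, gene_id)
    best = int(np.argmin(dist))  # first minimal |d| in (tss, gene_id) order
    row = recs.iloc[best]
    return str(row["gene_id"]), int(row["tss"] - mid)


def nearest_genes(regions: IntervalSet, tss: TssTable) -> pd.DataFrame:
    """Vectorized nearest-gene assignment for every region of a set."""
    rows = []
    for iv in regions:
        gid, d = nearest_gene(iv, tss)
        rows.append((iv.chrom, iv.start, iv.end, gid, d))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "distance"])


def _round_half_up(x: float, decimals: int = 1) -> float:
    scale = 10**decimals
    return np.floor(x * scale + 0.5) / scale


def overlap_fraction(
    a: IntervalSet, b: IntervalSet, min_bp: int = 1
) -> tuple[int, int, float]:
    """(count of a-intervals overlapping b, total, percentage to 1 decimal).

    Percentage is rounded half-up, e.g. 6129/8309 -> 73.8.
    """
    total = len(a)
    if total == 0:
        raise ValidationError("overlap percentage undefined for an empty set")
    count = int(overlaps(a, b, min_bp=min_bp).sum())
    return count, total, fraction_percent(count, total)


def fraction_percent(count: int, total: int) -> float:
    """100*count/total rounded half-up to one decimal place."""
    if total == 0:
        raise ValidationError("percentage undefined for total = 0")
    return float(_round_half_up(100.0 * count / total, 1))
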