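"""Readers and writers for BED, chrom-sizes, and TSS tables.

BED files are 3+ column, tab- or whitespace-separated, 0-based half-open.
Writing emits BED3, or BED5 (name ".", score column) when scores are given.
Round-trips are exact on coordinates.
"""

from __future__ import annotations

import os
from typing import Sequence

import pandas as pd

from .genomic import Genome, GenomicInterval, IntervalSet, TssTable, ValidationError


class BedParseError(ValueError):
    """A BED line failed to parse; message carries the 1-based line number."""


def read_chrom_sizes(path: str | os.PathLike) -> Genome:
    """Two-column (name, length) chromosome-size table."""
    chroms: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                length = int(fields[1])
            except ValueError:
                raise BedParseError(f"{path}:{lineno}: non-integer length {fields[1]!r}") from None
            chroms.append((fields[0], length))
    return Genome(tuple(chroms))


def write_chrom_sizes(genome: Genome, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chroms:
            fh.write(f"{name}\t{length}\n")


def iter_bed_records(path: str | os.PathLike):
    """Yield (lineno, chrom, start, end, strand) from a BED3+ file.

    Strand is taken from column 6 when present, else '.'. Track/browser/comment
    lines are skipped.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from None
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            if start >= end:
                raise BedParseError(f"{path}:{lineno}: start {start} >= end {end}")
            if start < 0:
                raise BedParseError(f"{path}:{lineno}: negative start {start}")
            yield lineno, chrom, start, end, strand


def read_bed(path: str | os.PathLike, genome: Genome | None = None) -> IntervalSet:
    """Parse a BED3+ file into a validated, sorted IntervalSet.

    Records on chromosomes absent from `genome`, or running past a chromosome
    end, raise ValidationError.
    """
    intervals = []
    for lineno, chrom, start, end, strand in iter_bed_records(path):
        if genome is not None:
            if chrom not in genome:
                raise ValidationError(f"{path}:{lineno}: unknown chromosome {chrom}")
            if end > genome.length(chrom):
                raise ValidationError(
                    f"{path}:{lineno}: interval end {end} past chromosome end "
                    f"{genome.length(chrom)}"
                )
        intervals.append(GenomicInterval(chrom, start, end, strand))
    return IntervalSet(intervals, genome=genome)


def write_bed(
    iset: IntervalSet,
    path: str | os.PathLike,
    scores: Sequence[float] | None = None,
) -> None:
    """Write BED3, or BED5 with name='.' when `scores` is given."""
    if scores is not None and len(scores) != len(iset):
        raise ValidationError(f"{len(scores)} scores for {len(iset)} intervals")
    with open(path, "w") as fh:
        for i, iv in enumerate(iset):
            if scores is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t{scores[i]:g}\n")


def read_tss_table(path: str | os.PathLike, genome: Genome | None = None) -> TssTable:
    """Tab-separated TSS table with header: gene_id, chrom, tss, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    return TssTable(df[["gene_id", "chrom", "tss", "strand"]].copy(), genome=genome)


def write_tss_table(tss: TssTable, path: str | os.PathLike) -> None:
    tss.records.to_csv(path, sep="\t", index=False)
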