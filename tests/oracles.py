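"""Brute-force reference implementations used only to check the package.

Everything here is deliberately naive — per-base coverage arrays, O(n^2)
all-pairs scans, direct probability summation — and stays independent of the
code paths it validates.
"""

from __future__ import annotations

import math

import numpy as np

from enhancerstate import Genome, GenomicInterval, IntervalSet


def merge_by_coverage(iset: IntervalSet, genome: Genome) -> list[tuple[str, int, int]]:
    """Reconstruct merged intervals from a boolean per-base coverage array."""
    out = []
    for chrom, length in genome.chroms:
        cov = np.zeros(length, dtype=bool)
        for iv in iset:
            if iv.chrom == chrom:
                cov[iv.start : iv.end] = True
        padded = np.concatenate(([False], cov, [False]))
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        for s, e in zip(edges[::2], edges[1::2]):
            out.append((chrom, int(s), int(e)))
    return out


def overlaps_all_pairs(a: IntervalSet, b: IntervalSet, min_bp: int = 1) -> list[bool]:
    flags = []
    for iv in a:
        hit = False
        for jv in b:
            if iv.chrom == jv.chrom and min(iv.end, jv.end) - max(iv.start, jv.start) >= min_bp:
                hit = True
                break
        flags.append(hit)
    return flags


def nearest_tss_exhaustive(region: GenomicInterval, records) -> tuple[str, int]:
    """records: iterable of (gene_id, chrom, tss)."""
    mid = (region.start + region.end) // 2
    best = None
    for gene_id, chrom, tss in records:
        if chrom != region.chrom:
            continue
        key = (abs(tss - mid), tss, gene_id)
        if best is None or key < best[0]:
            best = (key, gene_id, tss - mid)
    if best is None:
        return "unassigned", 0
    return best[1], best[2]


# ---------------------------------------------------------------------------
# naive island caller


def poisson_pmf(k: int, lam: float) -> float:
    return math.exp(-lam + k * math.log(lam) - math.lgamma(k + 1))


def poisson_upper_tail(k: int, lam: float) -> float:
    """P(X >= k) by direct summation of the complement."""
    return 1.0 - sum(poisson_pmf(j, lam) for j in range(k))


def naive_eligible_threshold(lam: float, window_p: float) -> int:
    l0 = 1
    while poisson_upper_tail(l0, lam) >= window_p:
        l0 += 1
    return l0


def naive_window_counts(positions, strands, length, window_bp, fragment_size):
    """Loop-based redundancy filter (threshold 1), shift, and window count."""
    shift = fragment_size // 2
    seen = set()
    n_windows = (length + window_bp - 1) // window_bp
    counts = [0] * n_windows
    for pos, strand in zip(positions, strands):
        if (pos, strand) in seen:
            continue
        seen.add((pos, strand))
        shifted = pos + shift if strand > 0 else pos - shift
        shifted = min(max(shifted, 0), length - 1)
        counts[shifted // window_bp] += 1
    return counts


def naive_islands(counts, l0, gap_windows, lam):
    """Linear scan over windows; returns [(first, last, score), ...]."""
    islands = []
    current: list[int] = []  # eligible window indices of the open island
    gap_run = 0
    for i, c in enumerate(counts):
        if c >= l0:
            if current and gap_run > gap_windows:
                islands.append(current)
                current = []
            current.append(i)
            gap_run = 0
        else:
            gap_run += 1
    if current:
        islands.append(current)
    out = []
    for elig in islands:
        score = sum(-math.log(poisson_pmf(counts[i], lam)) for i in elig)
        out.append((elig[0], elig[-1], score))
    return out


def venn_cells_bruteforce(sets: dict[str, IntervalSet], units: IntervalSet):
    cells: dict[frozenset, int] = {}
    for iv in units:
        members = []
        for name, s in sets.items():
            if any(iv.chrom == jv.chrom and min(iv.end, jv.end) > max(iv.start, jv.start)
                   for jv in s):
                members.append(name)
        if members:
            key = frozenset(members)
            cells[key] = cells.get(key, 0) + 1
    return cells
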