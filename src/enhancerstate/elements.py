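"""Histone-mark-based classification of regulatory elements.

Regions are classified into five states from their distance to the nearest
TSS and their overlap with histone-mark peak sets:

* proximal (midpoint within ``promoter_window_bp`` of a TSS) and carrying the
  active mark (H3K27ac) -> active_promoter;
* proximal without the active mark -> silent_promoter;
* distal with an enhancer mark (H3K4me1 or H3K4me2) and the active mark
  -> active_enhancer;
* distal with an enhancer mark only -> primed_enhancer;
* anything else -> other.

Adipogenic enhancers are active enhancers bound by any of the adipogenic
lineage-determining TFs (C/EBPalpha, C/EBPbeta, PPARgamma), partitioned into
C/EBP+PPARg-, C/EBP-PPARg+ and C/EBP+PPARg+ classes; adipogenic promoters
are the promoters nearest to adipogenic enhancers. The entire rule set is
data (a :class:`ClassificationRules` instance), not code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic import (
    GenomicInterval,
    IntervalSet,
    TssTable,
    ValidationError,
    overlaps,
)

ELEMENT_CLASSES = (
    "active_promoter",
    "silent_promoter",
    "active_enhancer",
    "primed_enhancer",
    "other",
)


class ConfigurationError(ValueError):
    pass


@dataclass
class ClassificationRules:
    promoter_window_bp: int = 2500
    enhancer_marks: tuple[str, ...] = ("H3K4me1", "H3K4me2")
    active_mark: str = "H3K27ac"
    # resolution order when a region satisfies several branches; the default
    # sends boundary-straddling regions down the promoter branch
    priority: tuple[str, ...] = ELEMENT_CLASSES

    def __post_init__(self) -> None:
        if self.promoter_window_bp <= 0:
            raise ValidationError("promoter_window_bp must be positive")
        if set(self.priority) != set(ELEMENT_CLASSES):
            raise ValidationError("priority must cover all element classes exactly")


def _require_marks(mark_sets: dict[str, IntervalSet], rules: ClassificationRules) -> None:
    needed = set(rules.enhancer_marks) | {rules.active_mark}
    missing = needed - set(mark_sets)
    if missing:
        raise ConfigurationError(f"missing mark sets: {sorted(missing)}")


def _tss_distance(regions: IntervalSet, tss: TssTable) -> np.ndarray:
    """Distance from each region midpoint to its nearest TSS (inf if none)."""
    per_chrom = {c: grp["tss"].to_numpy() for c, grp in tss.records.groupby("chrom")}
    dist = np.full(len(regions), np.inf)
    mids = (regions.start + regions.end) // 2
    for i in range(len(regions)):
        sites = per_chrom.get(str(regions.chrom[i]))
        if sites is not None and sites.size:
            dist[i] = np.abs(sites - mids[i]).min()
    return dist


def classify_regions(
    regions: IntervalSet,
    mark_sets: dict[str, IntervalSet],
    tss: TssTable,
    rules: ClassificationRules | None = None,
) -> pd.DataFrame:
    """Classify every region; returns a frame with a `element_class` column.

    Classification is total and deterministic: each region receives exactly
    one class.
    """
    rules = rules or ClassificationRules()
    _require_marks(mark_sets, rules)
    proximal = _tss_distance(regions, tss) <= rules.promoter_window_bp
    active = overlaps(regions, mark_sets[rules.active_mark])
    enh_mark = np.zeros(len(regions), dtype=bool)
    for mark in rules.enhancer_marks:
        enh_mark |= overlaps(regions, mark_sets[mark])

    classes = np.full(len(regions), "other", dtype=object)
    # later assignments win, so iterate priority from lowest to highest
    branch = {
        "active_promoter": proximal & active,
        "silent_promoter": proximal & ~active,
        "active_enhancer": ~proximal & enh_mark & active,
        "primed_enhancer": ~proximal & enh_mark & ~active,
        "other": ~proximal & ~enh_mark,
    }
    for cls in reversed(rules.priority):
        classes[branch[cls]] = cls

    out = regions.to_frame()
    out["element_class"] = classes
    return out


def classify_region(
    region: GenomicInterval,
    mark_sets: dict[str, IntervalSet],
    tss: TssTable,
    rules: ClassificationRules | None = None,
) -> str:
    df = classify_regions(IntervalSet([region]), mark_sets, tss, rules)
    return str(df["element_class"].iloc[0])


def genomic_distribution(
    regions: IntervalSet,
    mark_sets: dict[str, IntervalSet],
    tss: TssTable,
    rules: ClassificationRules | None = None,
) -> dict[str, tuple[int, float]]:
    """Per-class (count, fraction); fractions sum to 1."""
    if len(regions) == 0:
        raise ValidationError("genomic distribution undefined for an empty region set")
    df = classify_regions(regions, mark_sets, tss, rules)
    counts = df["element_class"].value_counts()
    total = len(df)
    return {
        cls: (int(counts.get(cls, 0)), counts.get(cls, 0) / total)
        for cls in ELEMENT_CLASSES
    }


ADIPO_TFS = ("CEBPA", "CEBPB", "PPARG")


def define_adipogenic_enhancers(
    active_enhancers: IntervalSet,
    tf_sets: dict[str, IntervalSet],
    cebp_names: tuple[str, str] = ("CEBPA", "CEBPB"),
    pparg_name: str = "PPARG",
) -> pd.DataFrame:
    """Flag TF binding on active enhancers and partition the adipogenic ones.

    An enhancer is adipogenic when bound by C/EBPalpha, C/EBPbeta or
    PPARgamma. Partition labels over adipogenic enhancers are mutually
    exclusive and exhaustive: C/EBP+PPARg-, C/EBP-PPARg+, C/EBP+PPARg+
    (C/EBP = alpha union beta).
    """
    needed = set(cebp_names) | {pparg_name}
    missing = needed - set(tf_sets)
    if missing:
        raise ConfigurationError(f"missing TF sets: {sorted(missing)}")

    out = active_enhancers.to_frame()
    for name, tf_set in tf_sets.items():
        out[name] = overlaps(active_enhancers, tf_set)
    cebp = np.zeros(len(out), dtype=bool)
    for name in cebp_names:
        cebp |= out[name].to_numpy()
    pparg = out[pparg_name].to_numpy()

    out["adipogenic"] = cebp | pparg
    labels = np.full(len(out), "", dtype=object)
    labels[cebp & ~pparg] = "C/EBP+PPARg-"
    labels[~cebp & pparg] = "C/EBP-PPARg+"
    labels[cebp & pparg] = "C/EBP+PPARg+"
    out["partition"] = labels
    return out


def adipogenic_promoters(
    adipogenic_enhancers: IntervalSet, promoters: IntervalSet
) -> IntervalSet:
    """Promoters nearest (midpoint distance) to adipogenic enhancers.

    Ties go to the lower-coordinate promoter; output is deduplicated.
    """
    if len(promoters) == 0:
        raise ValidationError("promoter set is empty")
    chosen: set[GenomicInterval] = set()
    prom_by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in promoters:
        prom_by_chrom.setdefault(p.chrom, []).append(p)
    for enh in adipogenic_enhancers:
        cands = prom_by_chrom.get(enh.chrom)
        if not cands:
            continue
        best = min(cands, key=lambda p: (abs(p.midpoint - enh.midpoint), p.start, p.end))
        chosen.add(best)
    return IntervalSet(chosen, genome=promoters.genome)
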