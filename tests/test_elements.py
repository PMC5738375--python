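"""Regulatory-element classification and adipogenic enhancer derivation."""

import numpy as np
import pandas as pd
import pytest

from enhancerstate import (
    ClassificationRules,
    GenomicInterval,
    IntervalSet,
    TssTable,
    ValidationError,
    adipogenic_promoters,
    classify_region,
    classify_regions,
    define_adipogenic_enhancers,
    genomic_distribution,
)
from enhancerstate.elements import ELEMENT_CLASSES, ConfigurationError


@pytest.fixture
def tss():
    return TssTable(
        pd.DataFrame(
            [("g1", "chr1", 10_000, "+"), ("g2", "chr1", 60_000, "-")],
            columns=["gene_id", "chrom", "tss", "strand"],
        )
    )


def _marks(**kwargs):
    base = {"H3K4me1": [], "H3K4me2": [], "H3K27ac": []}
    base.update(kwargs)
    return {k: IntervalSet(v) for k, v in base.items()}


class TestClassifyRegion:
    def test_distal_with_both_marks_is_active_enhancer(self, tss):
        region = GenomicInterval("chr1", 30_000, 31_000)
        marks = _marks(
            H3K4me1=[GenomicInterval("chr1", 30_000, 31_000)],
            H3K27ac=[GenomicInterval("chr1", 30_200, 30_800)],
        )
        assert classify_region(region, marks, tss) == "active_enhancer"

    def test_distal_with_enhancer_mark_only_is_primed(self, tss):
        region = GenomicInterval("chr1", 30_000, 31_000)
        marks = _marks(H3K4me1=[GenomicInterval("chr1", 30_000, 31_000)])
        assert classify_region(region, marks, tss) == "primed_enhancer"

    def test_h3k4me2_alone_also_marks_enhancer(self, tss):
        region = GenomicInterval("chr1", 30_000, 31_000)
        marks = _marks(H3K4me2=[GenomicInterval("chr1", 30_000, 31_000)])
        assert classify_region(region, marks, tss) == "primed_enhancer"

    def test_proximal_with_active_mark_is_active_promoter(self, tss):
        region = GenomicInterval("chr1", 9_000, 10_500)
        marks = _marks(H3K27ac=[GenomicInterval("chr1", 9_500, 10_000)])
        assert classify_region(region, marks, tss) == "active_promoter"

    def test_proximal_without_active_mark_is_silent_promoter(self, tss):
        region = GenomicInterval("chr1", 9_000, 10_500)
        # enhancer marks do not rescue a proximal region
        marks = _marks(H3K4me1=[GenomicInterval("chr1", 9_000, 10_500)])
        assert classify_region(region, marks, tss) == "silent_promoter"

    def test_distal_no_marks_is_other(self, tss):
        assert classify_region(GenomicInterval("chr1", 30_000, 31_000), _marks(), tss) == "other"

    def test_proximity_uses_midpoint(self, tss):
        # region end is near the TSS but the midpoint is 3 kb away -> distal
        region = GenomicInterval("chr1", 12_000, 14_000)
        assert classify_region(region, _marks(), tss) == "other"

    def test_missing_mark_set_is_configuration_error(self, tss):
        with pytest.raises(ConfigurationError):
            classify_region(GenomicInterval("chr1", 0, 10), {"H3K27ac": IntervalSet([])}, tss)

    def test_total_and_deterministic_under_shuffling(self, tss, rng):
        ivs = [
            GenomicInterval("chr1", int(s), int(s) + 800)
            for s in rng.integers(0, 90_000, size=60)
        ]
        marks = _marks(
            H3K4me1=[GenomicInterval("chr1", 20_000, 50_000)],
            H3K27ac=[GenomicInterval("chr1", 40_000, 70_000)],
        )
        a = classify_regions(IntervalSet(ivs), marks, tss)
        b = classify_regions(IntervalSet(list(reversed(ivs))), marks, tss)
        pd.testing.assert_frame_equal(a, b)
        assert set(a["element_class"]) <= set(ELEMENT_CLASSES)


class TestGenomicDistribution:
    def test_single_class(self, tss):
        regions = IntervalSet([GenomicInterval("chr1", 30_000 + i * 2000, 31_000 + i * 2000)
                               for i in range(10)])
        marks = _marks(
            H3K4me1=[GenomicInterval("chr1", 29_000, 52_000)],
            H3K27ac=[GenomicInterval("chr1", 29_000, 52_000)],
        )
        dist = genomic_distribution(regions, marks, tss)
        assert dist["active_enhancer"] == (10, 1.0)

    def test_fractions_sum_to_one(self, noiseless_dataset):
        ds = noiseless_dataset
        els = ds.truth.elements
        regions = IntervalSet(
            [GenomicInterval(str(r.chrom), int(r.start), int(r.end)) for r in els.itertuples()],
            genome=ds.genome,
        )
        dist = genomic_distribution(regions, ds.mark_sets, ds.tss)
        assert sum(f for _, f in dist.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(c for c, _ in dist.values()) == len(regions)

    def test_empty_regions_error(self, tss):
        with pytest.raises(ValidationError):
            genomic_distribution(IntervalSet([]), _marks(), tss)


class TestAdipogenicEnhancers:
    def _enh(self, *starts):
        return IntervalSet([GenomicInterval("chr1", s, s + 1000) for s in starts])

    def test_partition_labels(self):
        enh = self._enh(10_000, 20_000, 30_000, 40_000)
        tf_sets = {
            "CEBPA": IntervalSet([GenomicInterval("chr1", 30_200, 30_400)]),
            "CEBPB": IntervalSet([GenomicInterval("chr1", 10_200, 10_400)]),
            "PPARG": IntervalSet([
                GenomicInterval("chr1", 20_200, 20_400),
                GenomicInterval("chr1", 30_600, 30_800),
            ]),
        }
        out = define_adipogenic_enhancers(enh, tf_sets)
        assert out["partition"].tolist() == [
            "C/EBP+PPARg-", "C/EBP-PPARg+", "C/EBP+PPARg+", ""
        ]
        assert out["adipogenic"].tolist() == [True, True, True, False]

    def test_partition_exclusive_and_exhaustive(self, noiseless_dataset):
        ds = noiseless_dataset
        els = ds.truth.elements
        ae = els[els["element_class"] == "active_enhancer"]
        enh = IntervalSet(
            [GenomicInterval(str(r.chrom), int(r.start), int(r.end)) for r in ae.itertuples()],
            genome=ds.genome,
        )
        out = define_adipogenic_enhancers(enh, ds.tf_sets)
        adipo = out[out["adipogenic"]]
        assert (adipo["partition"] != "").all()
        assert (out.loc[~out["adipogenic"], "partition"] == "").all()

    def test_missing_tf_set(self):
        with pytest.raises(ConfigurationError):
            define_adipogenic_enhancers(self._enh(0), {"CEBPA": IntervalSet([])})


class TestAdipogenicPromoters:
    def test_nearest_promoter_chosen(self):
        enh = IntervalSet([GenomicInterval("chr1", 50_000, 51_000)])
        promoters = IntervalSet([
            GenomicInterval("chr1", 52_000, 52_500),   # 2 kb away
            GenomicInterval("chr1", 60_000, 60_500),   # 10 kb away
        ])
        out = adipogenic_promoters(enh, promoters)
        assert [(iv.start, iv.end) for iv in out] == [(52_000, 52_500)]

    def test_shared_nearest_promoter_deduplicated(self):
        enh = IntervalSet([
            GenomicInterval("chr1", 50_000, 51_000),
            GenomicInterval("chr1", 54_000, 55_000),
        ])
        promoters = IntervalSet([GenomicInterval("chr1", 52_000, 52_500)])
        assert len(adipogenic_promoters(enh, promoters)) == 1

    def test_matches_exhaustive_nearest(self, toy_genome, rng):
        from conftest import random_interval_set

        enh = random_interval_set(rng, toy_genome, 40)
        promoters = random_interval_set(rng, toy_genome, 15)
        out = adipogenic_promoters(enh, promoters)
        expected = set()
        for e in enh:
            cands = [p for p in promoters if p.chrom == e.chrom]
            if cands:
                expected.add(min(
                    cands, key=lambda p: (abs(p.midpoint - e.midpoint), p.start, p.end)
                ))
        assert set(out) == expected

    def test_empty_promoters_error(self):
        with pytest.raises(ValidationError):
            adipogenic_promoters(IntervalSet([]), IntervalSet([]))


def test_planted_element_states_recovered_exactly(noiseless_dataset):
    """Noise-free marks reproduce every planted element state."""
    ds = noiseless_dataset
    els = ds.truth.elements
    regions = IntervalSet(
        [GenomicInterval(str(r.chrom), int(r.start), int(r.end)) for r in els.itertuples()],
        genome=ds.genome,
    )
    df = classify_regions(regions, ds.mark_sets, ds.tss)
    merged = df.merge(els, on=["chrom", "start", "end"], suffixes=("_pred", "_true"))
    assert len(merged) == len(els)
    assert (merged["element_class_pred"] == merged["element_class_true"]).all()
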