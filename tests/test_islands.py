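"""Island caller: window counting, eligibility, scoring, calibration, the
knockout differential filter, and replicate intersection."""

import math

import numpy as np
import pytest
from scipy import stats

from enhancerstate import (
    Genome,
    GenomicInterval,
    IntervalSet,
    IslandParams,
    TagLibrary,
    ValidationError,
    call_islands,
    differential_ko_filter,
    replicate_high_confidence,
)
from enhancerstate.islands import (
    FORWARD,
    REVERSE,
    IslandCall,
    background_lambda,
    calibrate_score_threshold,
    count_tags_in_intervals,
    eligible_threshold,
    find_islands,
    islands_to_interval_set,
    read_tag_bed,
    score_island,
    shift_and_count_windows,
)
from enhancerstate.simulate import SimulationConfig, simulate_dataset, truth_compare

from conftest import random_interval_set
from oracles import naive_eligible_threshold, naive_islands, naive_window_counts


def _lib(genome, chrom_tags, fragment_size=200):
    tags = {
        c: (np.asarray(p, dtype=np.int64), np.asarray(s, dtype=np.int8))
        for c, (p, s) in chrom_tags.items()
    }
    return TagLibrary(genome, tags, fragment_size=fragment_size)


def _random_lib(rng, genome, n_tags, fragment_size=250):
    tags = {}
    for chrom, length in genome.chroms:
        n = int(rng.integers(0, n_tags))
        pos = rng.integers(0, length, size=n).astype(np.int64)
        strand = np.where(rng.random(n) < 0.5, FORWARD, REVERSE).astype(np.int8)
        tags[chrom] = (pos, strand)
    return TagLibrary(genome, tags, fragment_size=fragment_size)


class TestShiftAndCount:
    def test_forward_tag_lands_in_shifted_window(self):
        genome = Genome((("chr1", 1000),))
        lib = _lib(genome, {"chr1": ([10], [FORWARD])}, fragment_size=200)
        counts = shift_and_count_windows(lib, IslandParams())
        # 5' start 10 shifted by 100 -> position 110 -> window index 2
        assert counts["chr1"][2] == 1 and counts["chr1"].sum() == 1

    def test_duplicates_collapsed_at_threshold_one(self):
        genome = Genome((("chr1", 1000),))
        lib = _lib(genome, {"chr1": ([10, 10, 10, 10], [FORWARD] * 4)})
        counts = shift_and_count_windows(lib, IslandParams(redundancy_threshold=1))
        assert counts["chr1"].sum() == 1
        counts3 = shift_and_count_windows(lib, IslandParams(redundancy_threshold=3))
        assert counts3["chr1"].sum() == 3

    def test_opposite_strands_not_duplicates(self):
        genome = Genome((("chr1", 1000),))
        lib = _lib(genome, {"chr1": ([500, 500], [FORWARD, REVERSE])})
        counts = shift_and_count_windows(lib, IslandParams())
        assert counts["chr1"].sum() == 2

    def test_sum_matches_naive_recount(self, rng):
        genome = Genome((("chr1", 20_000),))
        lib = _random_lib(rng, genome, 500)
        params = IslandParams()
        counts = shift_and_count_windows(lib, params)["chr1"]
        pos, strand = lib.tags["chr1"]
        naive = naive_window_counts(
            pos.tolist(), strand.tolist(), 20_000, params.window_bp, lib.fragment_size
        )
        assert counts.tolist() == naive


class TestEligibleThreshold:
    def test_derived_example(self):
        # P(X>=1; 0.25) = 0.221 > 0.2 but P(X>=2) = 0.0265 < 0.2
        assert eligible_threshold(0.25, 0.2) == 2

    def test_loose_probability_keeps_singletons(self):
        assert eligible_threshold(0.25, 0.999) == 1

    @pytest.mark.parametrize("lam,p", [(4.0, 0.001), (0.1, 0.05), (2.0, 0.2), (10.0, 1e-6)])
    def test_matches_tail_summation_oracle(self, lam, p):
        assert eligible_threshold(lam, p) == naive_eligible_threshold(lam, p)


class TestFindIslands:
    def test_gap_bridged(self):
        counts = np.zeros(20, dtype=int)
        counts[[10, 11, 13]] = 5
        assert find_islands(counts, l0=2, gap_windows=1) == [(10, 13)]

    def test_gap_exceeded_splits(self):
        counts = np.zeros(20, dtype=int)
        counts[[10, 13]] = 5
        assert find_islands(counts, l0=2, gap_windows=1) == [(10, 10), (13, 13)]

    def test_empty(self):
        assert find_islands(np.zeros(10, dtype=int), l0=1, gap_windows=1) == []

    def test_matches_run_scan_oracle(self, rng):
        for _ in range(50):
            counts = rng.poisson(0.7, size=200)
            gap = int(rng.integers(0, 4))
            got = find_islands(counts, l0=2, gap_windows=gap)
            expect = [(f, l) for f, l, _ in naive_islands(counts.tolist(), 2, gap, 0.7)]
            assert got == expect


class TestScoreIsland:
    def test_single_window_closed_form(self):
        counts = np.array([0, 2, 0])
        expected = -math.log(math.exp(-0.25) * 0.25**2 / 2)
        assert score_island((1, 1), counts, 0.25, l0=2) == pytest.approx(expected)
        assert expected == pytest.approx(3.7157359, abs=1e-6)

    def test_additive_over_windows(self):
        counts = np.array([3, 0, 2])
        total = score_island((0, 2), counts, 0.5, l0=2)
        assert total == pytest.approx(
            score_island((0, 0), counts, 0.5, l0=2) + score_island((2, 2), counts, 0.5, l0=2)
        )

    def test_no_eligible_window_rejected(self):
        with pytest.raises(ValidationError):
            score_island((0, 1), np.array([1, 1]), 0.25, l0=2)


class TestCalibration:
    def test_deterministic_given_seed(self):
        genome = Genome((("chr1", 1_000_000),))
        params = IslandParams(seed=42)
        t1 = calibrate_score_threshold(genome, 10_000, params)
        t2 = calibrate_score_threshold(genome, 10_000, params)
        assert t1 == t2 > 0

    def test_infinite_evalue_keeps_everything(self):
        genome = Genome((("chr1", 100_000),))
        params = IslandParams(evalue=float("inf"))
        assert calibrate_score_threshold(genome, 5_000, params) == 0.0

    def test_reproducible_across_seeds_within_mc_error(self):
        genome = Genome((("chr1", 1_000_000),))
        thresholds = [
            calibrate_score_threshold(genome, 10_000, IslandParams(seed=s, evalue=50))
            for s in (1, 2, 3)
        ]
        spread = max(thresholds) - min(thresholds)
        assert spread < 0.15 * np.mean(thresholds)

    def test_background_library_yields_about_evalue_islands(self, rng):
        genome = Genome((("chr1", 2_000_000),))
        params = IslandParams(seed=9, evalue=50)
        n_islands = []
        for s in range(5):
            lib = TagLibrary(
                genome,
                {"chr1": (
                    np.sort(rng.integers(0, 2_000_000, size=20_000)).astype(np.int64),
                    np.where(rng.random(20_000) < 0.5, FORWARD, REVERSE).astype(np.int8),
                )},
            )
            n_islands.append(len(call_islands(lib, params)))
        # stochastic: expected ~evalue background islands survive the threshold
        assert 0.4 * params.evalue <= np.mean(n_islands) <= 2.0 * params.evalue


class TestCallIslands:
    def test_empty_library(self):
        genome = Genome((("chr1", 10_000),))
        lib = _lib(genome, {})
        assert call_islands(lib, IslandParams()) == []

    def test_planted_enriched_region_recovered(self, rng):
        genome = Genome((("chr1", 1_000_000),))
        rate = 5000 / 1e6
        n_bg = int(rate * 1_000_000)
        island = (400_000, 402_000)
        n_extra = int(19 * rate * (island[1] - island[0]))
        mids = np.concatenate([
            rng.integers(0, 1_000_000, size=n_bg),
            rng.integers(*island, size=n_extra),
        ])
        strand = np.where(rng.random(mids.size) < 0.5, FORWARD, REVERSE).astype(np.int8)
        pos = np.clip(mids - 125 * strand, 0, 999_999).astype(np.int64)
        lib = TagLibrary(genome, {"chr1": (pos, strand)})
        calls = call_islands(lib, IslandParams(seed=3))
        hits = [c for c in calls if c.interval.overlaps(GenomicInterval("chr1", *island))]
        assert len(hits) >= 1
        best = max(hits, key=lambda c: c.score)
        assert abs(best.interval.start - island[0]) <= 100
        assert abs(best.interval.end - island[1]) <= 100

    def test_islands_never_overlap_and_are_sorted(self, rng):
        genome = Genome((("chr1", 200_000), ("chr2", 100_000)))
        lib = _random_lib(rng, genome, 5_000)
        calls = call_islands(lib, IslandParams(), score_threshold=0.0)
        ivs = [c.interval for c in calls]
        assert ivs == sorted(ivs, key=lambda iv: (iv.chrom, iv.start))
        for a, b in zip(ivs, ivs[1:]):
            assert a.chrom != b.chrom or a.end < b.start


class TestDifferentialKoFilter:
    @staticmethod
    def _uniform_lib(rng, genome, n):
        pos = np.sort(rng.integers(0, genome.total_length, size=n)).astype(np.int64)
        strand = np.where(rng.random(n) < 0.5, FORWARD, REVERSE).astype(np.int8)
        return TagLibrary(genome, {genome.names[0]: (pos, strand)})

    def test_equal_counts_dropped(self, rng):
        genome = Genome((("chr1", 100_000),))
        # control and KO identical in the island region and library size
        mids = rng.integers(50_000, 52_000, size=200)
        bg = rng.integers(0, 100_000, size=300)
        def mk(seed):
            r = np.random.default_rng(seed)
            m = np.concatenate([mids, bg])
            s = np.where(r.random(m.size) < 0.5, FORWARD, REVERSE).astype(np.int8)
            p = np.clip(m - 125 * s, 0, 99_999).astype(np.int64)
            return TagLibrary(genome, {"chr1": (p, s)})
        islands = [IslandCall(GenomicInterval("chr1", 50_000, 52_000), 10.0)]
        kept = differential_ko_filter(islands, [mk(1)], mk(2), fdr=0.05)
        assert kept == []

    def test_strong_enrichment_retained_and_binomial_oracle(self):
        genome = Genome((("chr1", 10_000),))
        # 100 control vs 10 KO tags inside one island, equal library sizes
        c_pos = np.linspace(4000, 5990, 100).astype(np.int64)
        k_pos = np.linspace(4000, 5990, 10).astype(np.int64)
        strands = lambda n: np.full(n, FORWARD, dtype=np.int8)
        control = TagLibrary(genome, {"chr1": (c_pos, strands(100))}, fragment_size=0)
        ko_in = np.concatenate([k_pos, np.linspace(8000, 9500, 90).astype(np.int64)])
        ko = TagLibrary(genome, {"chr1": (np.sort(ko_in), strands(100))}, fragment_size=0)
        islands = [IslandCall(GenomicInterval("chr1", 4000, 6000), 5.0)]
        kept = differential_ko_filter(islands, [control], ko, fdr=1e-3)
        assert len(kept) == 1
        oracle_p = float(stats.binom.sf(99, 110, 0.5))
        assert kept[0].diff_p == pytest.approx(oracle_p, rel=1e-9)
        assert kept[0].counts == {"control": 100, "ko": 10}

    def test_bh_adjustment_is_monotone(self, default_dataset):
        ds = default_dataset
        params = IslandParams(seed=1)
        calls = call_islands(ds.libraries["control_rep1"], params)
        controls = [ds.libraries["control_rep1"], ds.libraries["control_rep2"]]
        differential_ko_filter(calls, controls, ds.libraries["ko"], fdr=0.5, params=params)
        annotated = [(c.diff_p, c.diff_q) for c in calls if c.diff_p is not None]
        annotated.sort()
        qs = [q for _, q in annotated]
        assert qs == sorted(qs)

    def test_invalid_fdr(self):
        with pytest.raises(ValidationError):
            differential_ko_filter([], [], None, fdr=1.5)


class TestReplicateHighConfidence:
    def test_union_of_overlapping_pair(self):
        r1 = IntervalSet([GenomicInterval("chr1", 0, 100)])
        r2 = IntervalSet([GenomicInterval("chr1", 50, 150)])
        hc = replicate_high_confidence(r1, r2)
        assert [(iv.start, iv.end) for iv in hc] == [(0, 150)]

    def test_intersection_mode(self):
        r1 = IntervalSet([GenomicInterval("chr1", 0, 100)])
        r2 = IntervalSet([GenomicInterval("chr1", 50, 150)])
        hc = replicate_high_confidence(r1, r2, mode="intersection")
        assert [(iv.start, iv.end) for iv in hc] == [(50, 100)]

    def test_disjoint_replicates_empty(self):
        r1 = IntervalSet([GenomicInterval("chr1", 0, 100)])
        r2 = IntervalSet([GenomicInterval("chr1", 200, 300)])
        assert len(replicate_high_confidence(r1, r2)) == 0

    def test_matches_pairwise_union_oracle(self, toy_genome, rng):
        r1 = random_interval_set(rng, toy_genome, 100)
        r2 = random_interval_set(rng, toy_genome, 100)
        hc = replicate_high_confidence(r1, r2)
        expected = []
        for iv in r1:
            partners = [jv for jv in r2
                        if iv.chrom == jv.chrom and min(iv.end, jv.end) > max(iv.start, jv.start)]
            if partners:
                expected.append(GenomicInterval(
                    iv.chrom,
                    min([iv.start] + [p.start for p in partners]),
                    max([iv.end] + [p.end for p in partners]),
                ))
        from enhancerstate import merge_intervals
        expect_set = merge_intervals(IntervalSet(expected, genome=toy_genome))
        assert hc == expect_set


def test_tag_bed_roundtrip(tmp_path, rng):
    genome = Genome((("chr1", 50_000),))
    n = 500
    pos = rng.integers(200, 49_800, size=n).astype(np.int64)
    strand = np.where(rng.random(n) < 0.5, FORWARD, REVERSE).astype(np.int8)
    lib = TagLibrary(genome, {"chr1": (pos, strand)})
    from enhancerstate.simulate import _write_tag_bed

    p = tmp_path / "tags.bed"
    _write_tag_bed(lib, p, read_length=50)
    back = read_tag_bed(p, genome)
    got = sorted(zip(*back.tags["chr1"]))
    assert got == sorted(zip(pos.tolist(), strand.tolist()))
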