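import numpy as np
import pytest

from sescreen import (
    Enhancer,
    EnhancerClass,
    EnhancerRanking,
    GeneModel,
    GenomicInterval,
    Peak,
    SignalTrack,
    call_super,
    define_candidates,
    quantify_and_rank,
    stitch,
    summarize_ranking,
    top_k_signal_fraction,
)


def peak(chrom, start, end, score=1.0):
    return Peak(GenomicInterval(chrom, start, end), score=score)


def gene(gid, chrom, tss):
    return GeneModel(gid, GenomicInterval(chrom, tss, tss + 1), expression=1.0)


class TestDefineCandidates:
    def test_tss_exclusion_is_midpoint_distance(self):
        # peak midpoint 5000; TSS at 7500 -> distance exactly 2500 -> excluded
        p = peak("chr1", 4000, 6000)
        assert define_candidates([p], [gene("G", "chr1", 7500)], []) == []
        # TSS at 7501 -> distance 2501 -> kept
        assert define_candidates([p], [gene("G", "chr1", 7501)], []) == [p]

    def test_tss_on_other_chromosome_ignored(self):
        p = peak("chr1", 4000, 6000)
        assert define_candidates([p], [gene("G", "chr2", 5000)], []) == [p]

    def test_k4me3_overlap_fraction_boundary(self):
        p = peak("chr1", 1000, 2000)  # length 1000
        half = [peak("chr1", 1000, 1500)]  # overlap 500 = 50% -> excluded
        assert define_candidates([p], [], half) == []
        under = [peak("chr1", 1000, 1499)]  # 49.9% -> kept
        assert define_candidates([p], [], under) == [p]

    def test_k4me3_max_single_peak_not_sum(self):
        # two 300 bp overlaps (sum 60%) but max single overlap 30% -> kept
        p = peak("chr1", 1000, 2000)
        k4 = [peak("chr1", 1000, 1300), peak("chr1", 1600, 1900)]
        assert define_candidates([p], [], k4) == [p]

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            define_candidates([], [], [], tss_exclusion_bp=-1)
        with pytest.raises(ValueError):
            define_candidates([], [], [], k4me3_overlap_fraction=1.5)


class TestStitch:
    def test_gap_boundary(self):
        a, b = peak("chr1", 0, 100), peak("chr1", 100 + 12500, 12700)
        assert len(stitch([a, b])) == 1  # gap exactly the stitch distance
        c = peak("chr1", 100 + 12501, 12701)
        assert len(stitch([a, c])) == 2

    def test_transitive_merge_and_hull(self):
        peaks = [peak("chr1", 0, 100), peak("chr1", 5000, 5100), peak("chr1", 10000, 10100)]
        merged = stitch(peaks)
        assert len(merged) == 1
        assert (merged[0].region.start, merged[0].region.end) == (0, 10100)
        assert len(merged[0].constituents) == 3

    def test_no_merge_across_chromosomes(self):
        assert len(stitch([peak("chr1", 0, 100), peak("chr2", 0, 100)])) == 2

    def test_idempotent(self):
        peaks = [peak("chr1", i * 1000, i * 1000 + 500) for i in range(5)]
        once = stitch(peaks)
        again = stitch([Peak(e.region) for e in once])
        assert [e.region for e in again] == [e.region for e in once]

    def test_results_separated_by_more_than_distance(self):
        rng = np.random.default_rng(1)
        starts = np.sort(rng.integers(0, 500_000, 200))
        peaks = [peak("chr1", int(s), int(s) + 200) for s in starts]
        merged = stitch(peaks, 5000)
        for prev, cur in zip(merged, merged[1:]):
            assert cur.region.start - prev.region.end > 5000


class TestQuantifyAndRank:
    def test_signal_and_ascending_ranks(self):
        track = SignalTrack.from_segments(
            [("chr1", 0, 1000, 2.0), ("chr1", 5000, 6000, 0.5)]
        )
        enhancers = stitch([peak("chr1", 0, 1000), peak("chr1", 5000, 6000)], 1000)
        ranking = quantify_and_rank(enhancers, track)
        assert [e.signal for e in ranking.enhancers] == [500.0, 2000.0]
        assert [e.rank for e in ranking.enhancers] == [1, 2]
        assert ranking.total_signal == 2500.0

    def test_control_subtraction_floors_at_zero(self):
        track = SignalTrack.from_segments([("chr1", 0, 1000, 1.0)])
        control = SignalTrack.from_segments([("chr1", 0, 1000, 5.0)])
        ranking = quantify_and_rank(stitch([peak("chr1", 0, 1000)]), track, control)
        assert ranking.enhancers[0].signal == 0.0


def ranking_from_signals(signals):
    enhancers = [
        Enhancer(
            region=GenomicInterval("chr1", i * 100_000, i * 100_000 + 1000),
            constituents=[peak("chr1", i * 100_000, i * 100_000 + 1000)],
            signal=float(s),
            rank=i + 1,
        )
        for i, s in enumerate(sorted(signals))
    ]
    return EnhancerRanking(enhancers=enhancers, total_signal=float(sum(signals)))


class TestCallSuper:
    def test_tangent_on_hockey_stick(self):
        # 20 near-flat + 3 high: the cutoff must isolate the high suffix
        signals = list(np.linspace(1, 2, 20)) + [50, 80, 100]
        called = call_super(ranking_from_signals(signals), method="tangent")
        assert len(called.super_enhancers) == 3
        assert called.method == "tangent"

    def test_super_is_suffix_and_strictly_above_cutoff(self):
        signals = list(np.linspace(1, 2, 30)) + [40, 60]
        called = call_super(ranking_from_signals(signals), method="tangent")
        klasses = [e.klass for e in called.enhancers]
        first_super = klasses.index(EnhancerClass.SUPER)
        assert all(k is EnhancerClass.SUPER for k in klasses[first_super:])
        for e in called.enhancers:
            if e.klass is EnhancerClass.SUPER:
                assert e.signal > called.cutoff_signal
            else:
                assert e.signal <= called.cutoff_signal

    def test_top_n(self):
        called = call_super(ranking_from_signals(range(1, 11)), method="top_n", n=4)
        assert len(called.super_enhancers) == 4
        assert {e.signal for e in called.super_enhancers} == {7, 8, 9, 10}

    def test_top_n_validation(self):
        with pytest.raises(ValueError):
            call_super(ranking_from_signals([1, 2]), method="top_n")
        with pytest.raises(ValueError):
            call_super(ranking_from_signals([1, 2]), method="top_n", n=5)

    def test_half_signal_minimal_top_set(self):
        # total 100; top enhancer alone (60) already exceeds half
        called = call_super(
            ranking_from_signals([10, 10, 20, 60]), method="half_signal"
        )
        assert len(called.super_enhancers) == 1
        # total 100; 40 < 50, 40+30 > 50 -> two supers
        called = call_super(
            ranking_from_signals([10, 20, 30, 40]), method="half_signal"
        )
        assert len(called.super_enhancers) == 2

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="unknown method"):
            call_super(ranking_from_signals([1, 2]), method="elbow")

    def test_tangent_needs_positive_signal(self):
        with pytest.raises(ValueError):
            call_super(ranking_from_signals([0, 0]), method="tangent")


class TestSummaries:
    def test_top_k_fraction(self):
        r = ranking_from_signals([10, 20, 30, 40])
        assert top_k_signal_fraction(r, 1) == pytest.approx(0.4)
        assert top_k_signal_fraction(r, 4) == 1.0
        with pytest.raises(ValueError):
            top_k_signal_fraction(r, 0)

    def test_summarize_requires_classes(self):
        with pytest.raises(ValueError, match="call_super"):
            summarize_ranking(ranking_from_signals([1, 2]))

    def test_summarize_contents(self):
        called = call_super(ranking_from_signals([1, 1, 1, 1, 50]), method="top_n", n=1)
        s = summarize_ranking(called)
        assert s["n_enhancers"] == 5
        assert s["n_super"] == 1
        assert s["super_signal_fraction"] == pytest.approx(50 / 54)


def test_ranking_rejects_descending_signals():
    enhancers = [
        Enhancer(
            region=GenomicInterval("chr1", i * 10_000, i * 10_000 + 100),
            constituents=[peak("chr1", i * 10_000, i * 10_000 + 100)],
            signal=s,
        )
        for i, s in enumerate([5.0, 1.0])
    ]
    with pytest.raises(ValueError, match="ascending"):
        EnhancerRanking(enhancers=enhancers, total_signal=6.0)
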