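import numpy as np
import pytest

from sescreen import (
    Enhancer,
    EnhancerClass,
    EnhancerRanking,
    GeneModel,
    GenomicInterval,
    Peak,
    RankedGeneList,
    assign_genes,
    enrichment_score,
    expression_by_class,
    gsea_permutation_p,
    rank_genes_by_enhancer_signal,
)
from sescreen.gsea import _es_from_hits


def ranked(ids, metrics):
    return RankedGeneList(ids=tuple(ids), metrics=np.asarray(metrics, dtype=float))


class TestRankedGeneList:
    def test_validation(self):
        with pytest.raises(ValueError, match="unique"):
            ranked(["A", "A"], [2, 1])
        with pytest.raises(ValueError, match="non-increasing"):
            ranked(["A", "B"], [1, 2])
        with pytest.raises(ValueError, match="mismatch"):
            ranked(["A"], [1, 2])


class TestEnrichmentScore:
    def test_hand_computed_example_weight_zero(self):
        # list of 4, set {A, B} at the top; w=0 -> hits add 1/2, misses 1/2
        lst = ranked(["A", "B", "C", "D"], [4, 3, 2, 1])
        res = enrichment_score(lst, {"A", "B"}, weight_exponent=0.0)
        assert res["running_sum"] == pytest.approx([0.5, 1.0, 0.5, 0.0])
        assert res["es"] == pytest.approx(1.0)

    def test_hand_computed_example_weight_one(self):
        # hits A (4) and C (2): denom 6 -> steps 4/6, -1/2, 2/6, -1/2
        lst = ranked(["A", "B", "C", "D"], [4, 3, 2, 1])
        res = enrichment_score(lst, {"A", "C"}, weight_exponent=1.0)
        assert res["running_sum"] == pytest.approx(
            [4 / 6, 4 / 6 - 0.5, 4 / 6 - 0.5 + 2 / 6, 0.0]
        )
        assert res["es"] == pytest.approx(4 / 6)

    def test_bottom_concentrated_set_negative(self):
        lst = ranked(["A", "B", "C", "D", "E"], [5, 4, 3, 2, 1])
        res = enrichment_score(lst, {"D", "E"})
        assert res["es"] < 0

    def test_tie_resolves_positive(self):
        # running sum [-1/2, 0, 1/2, 0]: symmetric excursion -> positive wins
        lst = ranked(["A", "B", "C", "D"], [4, 3, 2, 1])
        res = enrichment_score(lst, {"B", "C"}, weight_exponent=0.0)
        assert res["es"] == pytest.approx(0.5)

    def test_zero_metric_hits_fall_back_to_equal_weights(self):
        lst = ranked(["A", "B", "C", "D"], [3, 2, 0, 0])
        res = enrichment_score(lst, {"C", "D"}, weight_exponent=1.0)
        assert np.isfinite(res["es"])

    def test_disjoint_set_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            enrichment_score(ranked(["A"], [1]), {"Z"})

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            enrichment_score(ranked(["A", "B"], [2, 1]), {"A"}, weight_exponent=-1)

    def test_fast_path_agrees_with_running_sum(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(3, 40))
            metrics = np.sort(rng.normal(0, 2, n))[::-1]
            ids = [f"g{i}" for i in range(n)]
            lst = ranked(ids, metrics)
            k = int(rng.integers(1, n))
            hit_idx = np.sort(rng.choice(n, k, replace=False))
            gene_set = {ids[i] for i in hit_idx}
            for w in (0.0, 1.0, 1.5):
                slow = enrichment_score(lst, gene_set, w)["es"]
                fast = _es_from_hits(np.abs(metrics) ** w, hit_idx, n)
                assert fast == pytest.approx(slow, abs=1e-12)


class TestPermutationP:
    def test_deterministic_given_seed(self):
        lst = ranked([f"g{i}" for i in range(50)], np.arange(50, 0, -1))
        gene_set = {"g0", "g1", "g2", "g3"}
        a = gsea_permutation_p(lst, gene_set, n_permutations=200, seed=9)
        b = gsea_permutation_p(lst, gene_set, n_permutations=200, seed=9)
        assert a.es == b.es and a.p_value == b.p_value and a.nes == b.nes

    def test_top_set_significant(self):
        lst = ranked([f"g{i}" for i in range(100)], np.arange(100, 0, -1))
        res = gsea_permutation_p(lst, {f"g{i}" for i in range(8)}, n_permutations=200, seed=1)
        assert res.es > 0
        assert res.p_value < 0.05
        assert res.nes > 1

    def test_p_never_zero(self):
        lst = ranked([f"g{i}" for i in range(30)], np.arange(30, 0, -1))
        res = gsea_permutation_p(lst, {"g0", "g1"}, n_permutations=100, seed=2)
        assert res.p_value >= 1 / 101

    def test_validation(self):
        lst = ranked(["A", "B", "C"], [3, 2, 1])
        with pytest.raises(ValueError):
            gsea_permutation_p(lst, {"A"}, n_permutations=10)
        with pytest.raises(ValueError):
            gsea_permutation_p(lst, {"Z"})
        with pytest.raises(ValueError):
            gsea_permutation_p(lst, {"A", "B", "C"})


def make_assignment():
    def enh(start, end, signal, klass):
        iv = GenomicInterval("chr1", start, end)
        return Enhancer(region=iv, constituents=[Peak(iv)], signal=signal, klass=klass)

    enhancers = [
        enh(100_000, 102_000, 10.0, EnhancerClass.TYPICAL),
        enh(300_000, 302_000, 20.0, EnhancerClass.TYPICAL),
        enh(600_000, 630_000, 500.0, EnhancerClass.SUPER),
    ]
    ranking = EnhancerRanking(enhancers=enhancers, total_signal=530.0)
    genes = [
        GeneModel("GS", GenomicInterval("chr1", 640_000, 640_001), expression=20.0),
        GeneModel("GT1", GenomicInterval("chr1", 103_000, 103_001), expression=5.0),
        GeneModel("GT2", GenomicInterval("chr1", 303_000, 303_001), expression=4.0),
        # linked to both a typical and the super enhancer? no - distinct loci
        GeneModel("GBOTH", GenomicInterval("chr1", 310_000, 310_001), expression=3.0),
    ]
    return ranking, genes, assign_genes(ranking, genes)


class TestRankGenes:
    def test_max_over_links_descending(self):
        ranking, genes, assignment = make_assignment()
        lst = rank_genes_by_enhancer_signal(assignment, ranking)
        assert lst.ids[0] == "GS"
        assert lst.metrics[0] == 500.0
        assert list(lst.metrics) == sorted(lst.metrics, reverse=True)

    def test_ties_broken_by_gene_id(self):
        ranking, genes, assignment = make_assignment()
        lst = rank_genes_by_enhancer_signal(assignment, ranking)
        # GT2 and GBOTH share the same best enhancer signal (20.0)
        tied = [g for g, m in zip(lst.ids, lst.metrics) if m == 20.0]
        assert tied == sorted(tied)


class TestExpressionByClass:
    def test_summaries_and_one_sided_test(self):
        ranking, genes, assignment = make_assignment()
        # add more genes per class so the test can run
        extra = [
            GeneModel("GS2", GenomicInterval("chr1", 650_000, 650_001), expression=30.0),
        ]
        assignment = assign_genes(ranking, genes + extra)
        out = expression_by_class(genes + extra, assignment)
        assert out["super"]["n"] == 2
        assert out["super"]["median"] > out["typical"]["median"]
        assert out["test"] is not None
        assert 0 < out["test"].p_value <= 1

    def test_empty_class_rejected(self):
        ranking, genes, assignment = make_assignment()
        with pytest.raises(ValueError):
            expression_by_class([], assignment)
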