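"""Fold increase at feature classes, discrete binding, co-occupancy tables."""

import numpy as np
import pytest

from npstools.enrichment import bound_features, cooccupancy, fold_increase
from npstools.genome import ClusterSet, FeatureSet, GenomeDef, GenomicInterval, ValidationError

from .conftest import bitmap, cluster_from, random_intervals


def _features(genome, triples, label="TER"):
    return FeatureSet(
        label, genome, tuple((fid, GenomicInterval(c, s, e)) for fid, c, s, e in triples)
    )


class TestFoldIncrease:
    def test_saturating_feature_class_gives_fold_one(self, toy_genome):
        a = cluster_from(np.random.default_rng(0), toy_genome, 10, protein="A")
        f = _features(toy_genome, [("all", "chr1", 0, 10_000)])
        r = fold_increase(a, f)
        assert r.fold == pytest.approx(1.0)
        assert r.expected_overlap_bp == pytest.approx(a.total_bases)

    def test_constructed_tenfold_enrichment(self):
        # F occupies 5% of a 100 kb genome; A has half its bases inside F
        genome = GenomeDef((("chr1", 100_000),))
        f = _features(genome, [("f1", "chr1", 0, 5_000)])
        a = ClusterSet.from_intervals(
            "A",
            [GenomicInterval("chr1", 0, 1_000), GenomicInterval("chr1", 50_000, 51_000)],
            genome,
        )
        r = fold_increase(a, f)
        assert r.fold == pytest.approx(0.5 / 0.05)

    def test_empty_inputs_rejected(self, toy_genome):
        a = ClusterSet.from_intervals("A", [], toy_genome)
        f = _features(toy_genome, [("f1", "chr1", 0, 100)])
        with pytest.raises(ValidationError, match="undefined fold"):
            fold_increase(a, f)

    def test_montecarlo_mode_agrees_with_analytic_on_sparse_sets(self, toy_genome):
        a = cluster_from(np.random.default_rng(1), toy_genome, 8, max_len=200, protein="A")
        f = _features(toy_genome, [("f1", "chr1", 2_000, 3_000), ("f2", "chr1", 7_000, 7_500)])
        analytic = fold_increase(a, f, mode="analytic")
        mc = fold_increase(a, f, mode="montecarlo", n_iterations=2_000, seed=2)
        assert mc.empirical_p is not None
        assert mc.fold == pytest.approx(analytic.fold, rel=0.10)

    def test_fold_scale_consistent_under_genome_doubling(self):
        genome = GenomeDef((("chr1", 50_000),))
        doubled = GenomeDef((("chr1", 50_000), ("chr1b", 50_000)))
        ivs = [GenomicInterval("chr1", 1_000, 2_000), GenomicInterval("chr1", 9_000, 9_400)]
        f_ivs = [("f1", "chr1", 1_200, 1_800)]
        r1 = fold_increase(
            ClusterSet.from_intervals("A", ivs, genome), _features(genome, f_ivs)
        )
        ivs2 = ivs + [GenomicInterval("chr1b", i.start, i.end) for i in ivs]
        f_ivs2 = f_ivs + [("f1b", "chr1b", 1_200, 1_800)]
        r2 = fold_increase(
            ClusterSet.from_intervals("A", ivs2, doubled), _features(doubled, f_ivs2)
        )
        assert r2.fold == pytest.approx(r1.fold)


class TestBoundFeatures:
    def test_no_overlap_and_full_coverage(self, toy_genome):
        f = _features(toy_genome, [("f1", "chr1", 100, 200), ("f2", "chr1", 300, 400)])
        empty = ClusterSet.from_intervals("A", [], toy_genome)
        assert bound_features(empty, f) == ([], 0)
        everything = ClusterSet.from_intervals(
            "A", [GenomicInterval("chr1", 0, 10_000)], toy_genome
        )
        assert bound_features(everything, f) == (["f1", "f2"], 2)

    def test_min_overlap_threshold_monotone(self, toy_genome):
        f = _features(toy_genome, [("f1", "chr1", 100, 200)])
        a = ClusterSet.from_intervals("A", [GenomicInterval("chr1", 150, 160)], toy_genome)
        assert bound_features(a, f, min_overlap_bp=10)[1] == 1
        assert bound_features(a, f, min_overlap_bp=11)[1] == 0
        with pytest.raises(ValueError):
            bound_features(a, f, min_overlap_bp=0)

    @pytest.mark.parametrize("seed", range(5))
    def test_agreement_with_bitmap_oracle(self, toy_genome, seed):
        rng = np.random.default_rng(seed)
        raw = random_intervals(rng, toy_genome, 15, max_len=300)
        a = ClusterSet.from_intervals("A", raw, toy_genome)
        feats = [
            (f"f{i}", "chr1", int(s), int(s) + 120)
            for i, s in enumerate(rng.integers(0, 9_880, size=20))
        ]
        f = _features(toy_genome, feats)
        bm = bitmap(raw, toy_genome)["chr1"]
        for min_ov in (1, 30):
            ids, count = bound_features(a, f, min_overlap_bp=min_ov)
            oracle = sorted(fid for fid, _, s, e in feats if int(bm[s:e].sum()) >= min_ov)
            assert ids == oracle and count == len(oracle)


class TestCooccupancy:
    def _matrix(self, toy_genome, n_features, bound_by):
        """Features laid out on a grid; bound_by maps protein -> set of indices."""
        feats = [(f"TER{i:02d}", "chr1", i * 130, i * 130 + 100) for i in range(n_features)]
        f = _features(GenomeDef((("chr1", 130 * n_features + 10),)), feats)
        genome = f.genome
        sets = {}
        for protein, idxs in bound_by.items():
            ivs = [GenomicInterval("chr1", i * 130, i * 130 + 100) for i in sorted(idxs)]
            sets[protein] = ClusterSet.from_intervals(protein, ivs, genome)
        return cooccupancy(sets, f)

    def test_both_bound_percentages_match_hand_arithmetic(self, toy_genome):
        # 56 of 71 features bound by both proteins -> 78.87...%
        m = self._matrix(toy_genome, 71, {"Smc6": set(range(56)), "Top3": set(range(56))})
        assert m.bound_percent(("Smc6", "Top3")) == pytest.approx(100 * 56 / 71)
        # 67 of 71 -> 94.366...%
        m = self._matrix(toy_genome, 71, {"Top3": set(range(67)), "Rmi1": set(range(67))})
        assert m.bound_percent(("Top3", "Rmi1")) == pytest.approx(100 * 67 / 71)

    def test_percentages_sum_to_100(self, toy_genome):
        m = self._matrix(
            toy_genome,
            20,
            {"A": set(range(0, 12)), "B": set(range(6, 18)), "C": set(range(3, 9))},
        )
        assert sum(m.combination_counts.values()) == 20
        assert sum(m.combination_percent.values()) == pytest.approx(100.0)

    def test_everything_bound_is_single_combination(self, toy_genome):
        m = self._matrix(toy_genome, 10, {"A": set(range(10)), "B": set(range(10))})
        assert m.combination_counts == {("A", "B"): 10}
        assert m.combination_percent[("A", "B")] == pytest.approx(100.0)

    def test_empty_inputs_rejected(self, toy_genome):
        a = ClusterSet.from_intervals("A", [], toy_genome)
        with pytest.raises(ValidationError, match="at least one"):
            cooccupancy({"A": a}, _features(toy_genome, []))
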