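"""Co-localization score, randomization null, empirical p and Fisher test."""

import math

import numpy as np
import pytest

from npstools.coloc import (
    colocalization_test,
    fisher_colocalization_test,
    genome_coverage_percent,
    monte_carlo_pvalue,
    overlap_bases,
    randomize_placement,
)
from npstools.genome import ClusterSet, GenomeDef, GenomicInterval, ValidationError

from .conftest import bitmap, cluster_from, random_intervals


def _single(genome, start, end, protein="X", chrom="chr1"):
    return ClusterSet.from_intervals(protein, [GenomicInterval(chrom, start, end)], genome)


class TestOverlapBases:
    def test_simple_intersection(self, toy_genome):
        a = _single(toy_genome, 100, 200, "A")
        b = _single(toy_genome, 150, 250, "B")
        assert overlap_bases(a, b) == 50
        assert overlap_bases(b, a) == 50

    def test_self_overlap_is_total_bases(self, toy_genome):
        a = cluster_from(np.random.default_rng(0), toy_genome, 20)
        assert overlap_bases(a, a) == a.total_bases

    def test_mismatched_genomes_rejected(self, toy_genome, two_chrom_genome):
        a = _single(toy_genome, 0, 10)
        b = _single(two_chrom_genome, 0, 10)
        with pytest.raises(ValidationError, match="different genomes"):
            overlap_bases(a, b)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bitmap_and_oracle_bound(self, two_chrom_genome, seed):
        rng = np.random.default_rng(seed)
        raw_a = random_intervals(rng, two_chrom_genome, 20)
        raw_b = random_intervals(rng, two_chrom_genome, 20)
        a = ClusterSet.from_intervals("A", raw_a, two_chrom_genome)
        b = ClusterSet.from_intervals("B", raw_b, two_chrom_genome)
        ov = overlap_bases(a, b)
        bm_a, bm_b = bitmap(raw_a, two_chrom_genome), bitmap(raw_b, two_chrom_genome)
        expected = sum(int((bm_a[c] & bm_b[c]).sum()) for c in two_chrom_genome.names)
        assert ov == expected
        assert ov <= min(a.total_bases, b.total_bases)


class TestRandomizePlacement:
    def test_total_bases_and_counts_conserved(self, two_chrom_genome):
        a = cluster_from(np.random.default_rng(1), two_chrom_genome, 25)
        r = randomize_placement(a, seed=11)
        assert r.total_bases == a.total_bases
        assert r.n_clusters == a.n_clusters
        for chrom, s, e in a.per_chrom():
            rs, re = r.arrays(chrom)
            assert sorted((e - s).tolist()) == sorted((re - rs).tolist())

    def test_full_chromosome_interval_is_fixed_point(self, toy_genome):
        a = _single(toy_genome, 0, 10_000)
        r = randomize_placement(a, seed=0)
        assert list(r.intervals()) == [GenomicInterval("chr1", 0, 10_000)]

    def test_start_uniform_on_valid_range(self, toy_genome):
        # single 1 kb interval on a 10 kb chromosome: start ~ U{0..9000}
        a = _single(toy_genome, 0, 1_000)
        rng = np.random.default_rng(123)
        n = 5_000
        starts = np.array(
            [next(randomize_placement(a, rng).intervals()).start for _ in range(n)]
        )
        mean_expected = 9_000 / 2
        se = 9_001 / math.sqrt(12 * n)  # sd of U[0,9000] / sqrt(n)
        assert abs(starts.mean() - mean_expected) < 3 * se
        assert starts.min() >= 0 and starts.max() <= 9_000

    def test_dense_set_raises_and_allow_overlap_mode_works(self):
        genome = GenomeDef((("chr1", 1_000),))
        ivs = [GenomicInterval("chr1", i * 100, i * 100 + 95) for i in range(10)]
        a = ClusterSet.from_intervals("dense", ivs, genome)
        with pytest.raises(ValidationError, match="allow_overlap"):
            randomize_placement(a, seed=0, max_tries=50)
        r = randomize_placement(a, seed=0, allow_overlap=True)
        assert r.total_bases <= a.total_bases  # collisions merge


class TestMonteCarlo:
    def test_empty_b_gives_p_one(self, toy_genome):
        a = _single(toy_genome, 0, 500, "A")
        b = ClusterSet.from_intervals("B", [], toy_genome)
        null, p = monte_carlo_pvalue(a, b, n_iterations=50, seed=1)
        assert overlap_bases(a, b) == 0
        assert np.all(null.scores == 0)
        assert p == 1.0  # ties count as >=

    def test_saturating_a_gives_p_one(self, toy_genome):
        a = _single(toy_genome, 0, 10_000, "A")
        b = cluster_from(np.random.default_rng(3), toy_genome, 10, protein="B")
        null, p = monte_carlo_pvalue(a, b, n_iterations=50, seed=2, randomize="b")
        assert np.all(null.scores == b.total_bases)
        assert p == 1.0

    def test_add_one_floor(self, toy_genome):
        a = _single(toy_genome, 0, 100, "A")
        b = _single(toy_genome, 0, 100, "B")
        _, p = monte_carlo_pvalue(a, b, n_iterations=99, seed=4)
        assert p >= 1 / 100

    def test_empirical_p_matches_exhaustive_enumeration(self):
        # A and B single 100 bp intervals on a 1 kb chromosome. Enumerate
        # all 901 placements of A to get the exact null tail probability.
        genome = GenomeDef((("chr1", 1_000),))
        a = _single(genome, 350, 450, "A")
        b = _single(genome, 400, 500, "B")
        observed = overlap_bases(a, b)
        tail = sum(
            1
            for s in range(0, 901)
            if max(0, min(s + 100, 500) - max(s, 400)) >= observed
        )
        exact = tail / 901
        n = 5_000
        _, p = monte_carlo_pvalue(a, b, n_iterations=n, seed=5)
        se = math.sqrt(exact * (1 - exact) / n)
        assert abs(p - exact) < 4 * se + 1 / n

    def test_bit_reproducible_given_seed(self, two_chrom_genome):
        a = cluster_from(np.random.default_rng(6), two_chrom_genome, 15, protein="A")
        b = cluster_from(np.random.default_rng(7), two_chrom_genome, 15, protein="B")
        n1, p1 = monte_carlo_pvalue(a, b, n_iterations=200, seed=42)
        n2, p2 = monte_carlo_pvalue(a, b, n_iterations=200, seed=42)
        assert np.array_equal(n1.scores, n2.scores) and p1 == p2
        n3, _ = monte_carlo_pvalue(a, b, n_iterations=200, seed=43)
        assert not np.array_equal(n1.scores, n3.scores)

    def test_rejects_bad_iteration_count(self, toy_genome):
        a = _single(toy_genome, 0, 10, "A")
        with pytest.raises(ValueError):
            monte_carlo_pvalue(a, a, n_iterations=0, seed=0)


def _enumerate_fisher_tail(a, b, c, d):
    """Brute-force P(X >= a) over all 2x2 tables with the same margins."""
    r1, c1, g = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - g), min(r1, c1)
    weights = {x: math.comb(r1, x) * math.comb(g - r1, c1 - x) for x in range(lo, hi + 1)}
    total = sum(weights.values())
    return sum(w for x, w in weights.items() if x >= a) / total


class TestFisher:
    def test_fully_nested_small_table(self):
        # A = B = 5 bases of a 10 bp genome: table (5,0,0,5), p = 1/C(10,5)
        genome = GenomeDef((("chr1", 10),))
        a = _single(genome, 0, 5, "A")
        b = _single(genome, 0, 5, "B")
        assert fisher_colocalization_test(a, b) == pytest.approx(1 / 252)

    def test_independence_table_not_significant(self):
        # table (1,1,1,1) on a 4 bp genome: observed equals expectation
        genome = GenomeDef((("chr1", 4),))
        a = _single(genome, 0, 2, "A")
        b = _single(genome, 1, 3, "B")
        assert fisher_colocalization_test(a, b) > 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_full_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(5):
            g = int(rng.integers(20, 201))
            na = int(rng.integers(1, g // 2))
            nb = int(rng.integers(1, g // 2))
            shared = int(rng.integers(0, min(na, nb) + 1))
            genome = GenomeDef((("chr1", g),))
            a = _single(genome, 0, na, "A")
            b = _single(genome, na - shared, na - shared + nb, "B")
            p = fisher_colocalization_test(a, b)
            oracle = _enumerate_fisher_tail(shared, na - shared, nb - shared, g - na - nb + shared)
            assert p == pytest.approx(oracle, rel=1e-9)


class TestCoverage:
    def test_empty_and_full(self, toy_genome):
        assert genome_coverage_percent(ClusterSet.from_intervals("X", [], toy_genome)) == 0
        assert genome_coverage_percent(_single(toy_genome, 0, 10_000)) == 100

    def test_fractional(self):
        genome = GenomeDef(tuple((f"chr{i}", 750_000) for i in range(1, 17)))
        a = _single(genome, 0, 500_000)
        assert genome_coverage_percent(a) == pytest.approx(100 * 500_000 / 12_000_000)


class TestFullResult:
    def test_bundles_both_statistics(self, toy_genome):
        a = cluster_from(np.random.default_rng(8), toy_genome, 10, protein="A")
        r = colocalization_test(a, a, n_iterations=100, seed=9)
        assert r.observed_overlap_bp == a.total_bases
        assert r.fold > 1
        assert 0 < r.empirical_p <= 1 and 0 < r.fisher_p <= 1
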