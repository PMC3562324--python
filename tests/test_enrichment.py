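"""Hypergeometric tail statistic, cluster enumeration, merging and summaries.

The tail probability is checked against exact rational arithmetic
(math.comb + Fraction) and against scipy's survival function — both
independent of the log-factorial implementation under test.
"""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom as scipy_hypergeom

import cazyclust as cz
from cazyclust.enrichment import EnrichmentParams

from conftest import build_genome


def exact_tail(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k) by exact binomial-coefficient arithmetic."""
    total = comb(N, n)
    acc = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    return Fraction(acc, total)


class TestHypergeomTail:
    @pytest.mark.parametrize(
        "N,K,n,k,expected",
        [
            (50, 10, 5, 5, Fraction(252, 2118760)),  # C(10,5)/C(50,5)
            (20, 5, 4, 2, Fraction(1205, 4845)),  # enumeration over all C(20,4) draws
            (100, 30, 10, 0, Fraction(1)),
        ],
    )
    def test_known_values(self, N, K, n, k, expected):
        assert cz.hypergeom_tail(N, K, n, k) == pytest.approx(
            float(expected), rel=1e-12
        )

    def test_matches_exact_rational_arithmetic_to_1e10(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            N = int(rng.integers(2, 10_000))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            got = cz.hypergeom_tail(N, K, n, k)
            want = float(exact_tail(N, K, n, k))
            assert got == pytest.approx(want, rel=1e-10)

    def test_matches_scipy_survival_function(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            N = int(rng.integers(2, 5000))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(1, min(n, K) + 1))
            sf = float(scipy_hypergeom.sf(k - 1, N, K, n))
            assert cz.hypergeom_tail(N, K, n, k) == pytest.approx(sf, rel=1e-9)

    @pytest.mark.parametrize(
        "N,K,n,k",
        [(10, 11, 5, 2), (10, 5, 11, 2), (10, 5, 5, 6), (10, 5, 3, -1)],
    )
    def test_invalid_arguments_fatal(self, N, K, n, k):
        with pytest.raises(ValueError):
            cz.hypergeom_tail(N, K, n, k)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_monotonicity(self, data):
        """Non-increasing in k at fixed (N,K,n); non-decreasing in n at fixed k."""
        N = data.draw(st.integers(2, 200))
        K = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, N))
        k = data.draw(st.integers(1, min(n, K)))
        p = cz.hypergeom_tail(N, K, n, k)
        # tolerance covers logsumexp roundoff (~1e-13 near P = 1)
        if k + 1 <= min(n, K):
            assert cz.hypergeom_tail(N, K, n, k + 1) <= p + 1e-12
        if n + 1 <= N and k <= min(n + 1, K):
            assert cz.hypergeom_tail(N, K, n + 1, k) >= p - 1e-12

    def test_extreme_tail_stays_positive(self):
        # log-space evaluation keeps astronomically small tails finite
        p = cz.hypergeom_tail(10_000, 400, 50, 50)
        assert 0 < p < 1e-60


class TestEnumerateCandidates:
    def test_all_label_bounded_windows(self):
        genome = build_genome({"s1": "NNPNNPNP"})  # labels at ordinals 2, 5, 7
        cands = cz.enumerate_candidates(genome, EnrichmentParams())
        bounds = [(c.first_ordinal, c.last_ordinal) for c in cands]
        assert bounds == [(2, 5), (2, 7), (5, 7)]
        by_bounds = {(c.first_ordinal, c.last_ordinal): c for c in cands}
        assert by_bounds[(2, 7)].n_window == 6 and by_bounds[(2, 7)].k_hits == 3

    @pytest.mark.parametrize("pattern", ["NNNN", "NPNN"])
    def test_fewer_than_two_labels_gives_nothing(self, pattern):
        genome = build_genome({"s1": pattern})
        assert cz.enumerate_candidates(genome) == []

    def test_window_cap_excludes_distant_pairs(self):
        pattern = "P" + "N" * 59 + "P"  # labels at 0 and 60
        genome = build_genome({"s1": pattern})
        assert cz.enumerate_candidates(genome, EnrichmentParams(max_window_genes=50)) == []
        assert len(cz.enumerate_candidates(genome, EnrichmentParams(max_window_genes=61))) == 1

    def test_pvalues_against_direct_formula(self):
        genome = build_genome({"s1": "PPNPN", "s2": "NPPNN"})
        N, K = genome.n_genes, genome.k_cazyme
        for c in cz.enumerate_candidates(genome):
            want = float(exact_tail(N, K, c.n_window, c.k_hits))
            assert c.p_value == pytest.approx(want, rel=1e-10)


class TestSignificantClusters:
    def _cluster(self, p):
        return cz.CandidateCluster("s1", 0, 1, 2, 2, p)

    def test_threshold_is_inclusive(self):
        kept = cz.significant_clusters([self._cluster(0.001)], EnrichmentParams())
        assert len(kept) == 1

    def test_above_threshold_dropped(self):
        assert cz.significant_clusters([self._cluster(0.0011)], EnrichmentParams()) == []

    def test_empty_input(self):
        assert cz.significant_clusters([], EnrichmentParams()) == []

    def test_bonferroni_divides_alpha(self):
        clusters = [self._cluster(0.001), self._cluster(0.0004)]
        kept = cz.significant_clusters(
            clusters, EnrichmentParams(alpha=0.001, bonferroni=True)
        )
        assert [c.p_value for c in kept] == [0.0004]


class TestMergeRegions:
    def _mk(self, genome, first, last):
        scaffold = genome.scaffolds[0]
        flags = [g.is_cazyme for g in scaffold.genes]
        k = sum(flags[first : last + 1])
        return cz.CandidateCluster("s1", first, last, last - first + 1, max(k, 2), 1e-6)

    def test_overlapping_clusters_union(self):
        genome = build_genome({"s1": "P" * 31})
        regions = cz.merge_regions(
            [self._mk(genome, 10, 20), self._mk(genome, 15, 30)], genome
        )
        assert len(regions) == 1
        assert (regions[0].first_ordinal, regions[0].last_ordinal) == (10, 30)
        # bp bounds span member genes
        assert regions[0].start == genome.scaffolds[0].genes[10].start
        assert regions[0].end == genome.scaffolds[0].genes[30].end

    def test_disjoint_clusters_stay_separate(self):
        genome = build_genome({"s1": "P" * 46})
        regions = cz.merge_regions(
            [self._mk(genome, 2, 5), self._mk(genome, 40, 45)], genome
        )
        assert [(r.first_ordinal, r.last_ordinal) for r in regions] == [(2, 5), (40, 45)]

    def test_different_scaffolds_never_merge(self):
        genome = build_genome({"s1": "PPPP", "s2": "PPPP"})
        c1 = cz.CandidateCluster("s1", 0, 3, 4, 4, 1e-6)
        c2 = cz.CandidateCluster("s2", 0, 3, 4, 4, 1e-6)
        assert len(cz.merge_regions([c1, c2], genome)) == 2

    def test_min_p_and_label_count(self):
        genome = build_genome({"s1": "PPNPP"})
        c1 = cz.CandidateCluster("s1", 0, 1, 2, 2, 1e-4)
        c2 = cz.CandidateCluster("s1", 1, 4, 4, 4, 1e-8)
        (region,) = cz.merge_regions([c1, c2], genome)
        assert region.min_p == 1e-8
        assert region.n_label_genes == 4  # distinct labelled genes in the union

    def test_top_regions_keeps_smallest_p(self):
        genome = build_genome({"s1": "PP", "s2": "PP"})
        c1 = cz.CandidateCluster("s1", 0, 1, 2, 2, 1e-4)
        c2 = cz.CandidateCluster("s2", 0, 1, 2, 2, 1e-9)
        regions = cz.merge_regions(
            [c1, c2], genome, EnrichmentParams(top_regions=1)
        )
        assert [r.scaffold_id for r in regions] == ["s2"]


class TestSummarizeRegions:
    def test_no_regions(self):
        genome = build_genome({"s1": "PP"})
        s = cz.summarize_regions([], genome)
        assert (s.total_length_bp, s.genome_fraction_pct, s.label_gene_fraction_pct) == (0, 0.0, 0.0)

    def test_zero_genome_length_fatal(self):
        genome = cz.GenomeModel(scaffolds=[])
        with pytest.raises(ValueError):
            cz.summarize_regions([], genome)

    def test_fractions_roundtrip_from_regions(self):
        genome = build_genome({"s1": "PPPPNNNNNN"}, gene_len=1000, gap=0)
        cands = cz.enumerate_candidates(genome)
        sig = cz.significant_clusters(cands, EnrichmentParams(alpha=1e-1))
        regions = cz.merge_regions(sig, genome)
        s = cz.summarize_regions(regions, genome)
        assert s.total_length_bp == sum(r.length_bp for r in regions)
        assert s.label_genes_in_regions == 4
        assert s.label_gene_fraction_pct == 100.0


def test_determinism_identical_region_tables():
    """Identical inputs must produce byte-identical tables."""
    from cazyclust.enrichment import regions_table

    genome = build_genome({"s1": "PPNPPPNNPP"})
    tables = []
    for _ in range(2):
        c = cz.enumerate_candidates(genome)
        s = cz.significant_clusters(c, EnrichmentParams(alpha=0.5))
        tables.append(regions_table(cz.merge_regions(s, genome)).to_csv())
    assert tables[0] == tables[1]
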