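"""Adjacent enzyme-gene runs and the alignment-based paralogy screen."""

import numpy as np
import pytest
from Bio import Align
from hypothesis import given, settings
from hypothesis import strategies as st

import cazyclust as cz
from cazyclust.adjacency import ParalogyParams, alignment_score, is_paralog_pair

from conftest import build_genome


def brute_force_best_score(a, b, match=1, mismatch=-1, gap=-2):
    """Plain recursion over every alignment path (no DP) — tiny inputs only."""

    def rec(i, j):
        if i == len(a) and j == len(b):
            return 0
        best = -(10**9)
        if i < len(a) and j < len(b):
            best = max(best, (match if a[i] == b[j] else mismatch) + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, gap + rec(i + 1, j))
        if j < len(b):
            best = max(best, gap + rec(i, j + 1))
        return best

    return rec(0, 0)


def random_protein(n, seed):
    return "".join(np.random.default_rng(seed).choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))


class TestFindAdjacentRuns:
    def test_pair_and_triplet(self):
        genome = build_genome({"s1": "PPNPPP"}, label="pcwde")
        runs = cz.find_adjacent_runs(genome, "pcwde")
        assert [(r.ordinals[0], r.run_length) for r in runs] == [(0, 2), (3, 3)]

    def test_isolated_genes_give_no_runs(self):
        genome = build_genome({"s1": "PNPN"}, label="pcwde")
        assert cz.find_adjacent_runs(genome, "pcwde") == []

    def test_quadruplet_reported_once(self):
        genome = build_genome({"s1": "PPPP"}, label="pcwde")
        runs = cz.find_adjacent_runs(genome, "pcwde")
        assert len(runs) == 1 and runs[0].run_length == 4

    def test_runs_disjoint_and_bounded_by_label_count(self):
        genome = build_genome({"s1": "PPNPPPNPP", "s2": "PPPPN"}, label="pcwde")
        runs = cz.find_adjacent_runs(genome, "pcwde")
        seen = set()
        for r in runs:
            keys = {(r.scaffold_id, o) for o in r.ordinals}
            assert not keys & seen
            seen |= keys
        assert sum(r.run_length for r in runs) <= genome.k_pcwde


class TestGlobalIdentity:
    def test_identical_sequences(self):
        ident, cov = cz.global_identity("MKVLIT", "MKVLIT")
        assert (ident, cov) == (100.0, 100.0)

    def test_single_substitution(self):
        ident, cov = cz.global_identity("ACDEFG", "ACDQFG")
        assert ident == pytest.approx(100 * 5 / 6)
        assert cov == 100.0

    def test_disjoint_alphabets(self):
        ident, _ = cz.global_identity("AAAA", "CCCC")
        assert ident == 0.0

    def test_empty_sequence_fatal(self):
        with pytest.raises(ValueError):
            cz.global_identity("", "ACD")

    def test_gap_columns_in_identity_denominator(self):
        # best alignment of ACDEF vs ACF keeps the three matches with 2 gaps
        ident, cov = cz.global_identity("ACDEF", "ACF")
        assert ident == pytest.approx(100 * 3 / 5)
        assert cov == pytest.approx(100.0)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        a=st.text(alphabet="ACDE", min_size=1, max_size=5),
        b=st.text(alphabet="ACDE", min_size=1, max_size=5),
    )
    def test_score_matches_exhaustive_path_enumeration(self, a, b):
        assert alignment_score(a, b) == brute_force_best_score(a, b)

    def test_score_matches_biopython_global_aligner(self):
        aligner = Align.PairwiseAligner(
            mode="global",
            match_score=1,
            mismatch_score=-1,
            open_gap_score=-2,
            extend_gap_score=-2,
        )
        rng = np.random.default_rng(5)
        for i in range(30):
            la, lb = rng.integers(5, 120, size=2)
            a, b = random_protein(la, 100 + i), random_protein(lb, 200 + i)
            assert alignment_score(a, b) == int(aligner.score(a, b))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        a=st.text(alphabet="ACDEFG", min_size=1, max_size=8),
        b=st.text(alphabet="ACDEFG", min_size=1, max_size=8),
    )
    def test_symmetry(self, a, b):
        assert cz.global_identity(a, b) == pytest.approx(cz.global_identity(b, a))


class TestFlagParalogousRuns:
    def _run(self, gene_ids):
        return cz.AdjacentRun(
            scaffold_id="s1", ordinals=list(range(len(gene_ids))), gene_ids=gene_ids
        )

    def test_identical_proteins_flagged(self):
        seq = random_protein(150, 1)
        runs = cz.flag_paralogous_runs(
            [self._run(["a", "b"])], {"a": seq, "b": seq}
        )
        assert runs[0].contains_paralog_pair is True
        assert runs[0].paralog_pairs == [("a", "b")]

    def test_unrelated_random_proteins_not_flagged(self):
        runs = cz.flag_paralogous_runs(
            [self._run(["a", "b"])],
            {"a": random_protein(200, 2), "b": random_protein(200, 3)},
        )
        assert runs[0].contains_paralog_pair is False

    def test_missing_protein_leaves_unknown(self):
        runs = cz.flag_paralogous_runs([self._run(["a", "b"])], {"a": "MKV"})
        assert runs[0].contains_paralog_pair is None

    def test_group_table_overrides_alignment(self):
        # unrelated sequences, but a shared precomputed group
        runs = cz.flag_paralogous_runs(
            [self._run(["a", "b"])],
            {"a": random_protein(100, 4), "b": random_protein(100, 5)},
            paralog_groups={"a": "fam1", "b": "fam1"},
        )
        assert runs[0].contains_paralog_pair is True

    def test_simulated_duplicate_pair_is_the_only_flagged_run(self):
        # two adjacent labelled pairs; only one is an injected duplication
        spec = cz.SyntheticGenomeSpec(
            n_scaffolds=1,
            genes_per_scaffold=40,
            background_label_rate=0.0,
            seed=13,
            planted_clusters=[
                cz.PlantedCluster(0, 5, 2, 2),
                cz.PlantedCluster(0, 20, 2, 2),
            ],
            paralog_injections=[cz.ParalogInjection(0, 20, 21, mutation_rate=0.05)],
        )
        genome, proteins, truth = cz.simulate_genome_model(spec)
        runs = cz.find_adjacent_runs(genome, "cazyme")
        cz.flag_paralogous_runs(runs, proteins)
        flagged = [r for r in runs if r.contains_paralog_pair]
        assert len(runs) == 2
        assert len(flagged) == 1
        assert flagged[0].gene_ids == truth["paralog_pairs"][0]


def test_paralogy_params_validation():
    with pytest.raises(ValueError):
        ParalogyParams(min_identity_pct=0)
    assert is_paralog_pair("MKVLIT", "MKVLIT")
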