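"""The summary-statistic battery against its naive string-based oracle."""

import numpy as np
import pytest

from matesim import (
    EmptyPanelError,
    SequencePanel,
    StatisticsError,
    allelic_het,
    collect_panel,
    encode,
    found_population,
    haplotypes,
    nei_het,
    pairwise_pi,
    seg_sites,
    summarize,
    watterson,
)
from matesim import stats_naive as naive
from matesim.genetics import LocusClass

from conftest import random_dna


def panel_of(strings):
    return SequencePanel.from_sequences([encode(s) for s in strings])


def random_panel(rng, max_n=10, max_len=50):
    n = int(rng.integers(2, max_n + 1))
    length = int(rng.integers(2, max_len + 1))
    pool_size = int(rng.integers(1, n + 1))
    pool = [random_dna(rng, length) for _ in range(pool_size)]
    return [pool[int(i)] for i in rng.integers(0, pool_size, size=n)]


class TestClosedFormExamples:
    def test_two_sequences_three_differences(self):
        a = "A" * 100
        b = "C" * 3 + "A" * 97
        panel = panel_of([a, b])
        stats = summarize(panel)
        assert stats.S == 3
        assert stats.theta_w == 3.0          # a_2 = 1
        assert stats.pi == 3.0
        assert stats.h == 2
        assert stats.H_A == 1.0              # unbiased: 2 * (1 - 1/2) = 1
        assert stats.H_N == pytest.approx(0.015)

    def test_watterson_harmonic_sum(self):
        """n=4, S=11 -> theta_w = 11 / (1 + 1/2 + 1/3) = 6."""
        seqs = ["A" * 11, "C" * 11, "G" * 11, "T" * 8 + "G" * 3]
        panel = panel_of(seqs)
        assert seg_sites(panel) == 11
        assert watterson(panel) == pytest.approx(6.0)

    def test_monomorphic_panel(self):
        stats = summarize(panel_of(["ACGT"] * 5))
        assert (stats.S, stats.pi, stats.h, stats.H_A, stats.H_N) == (0, 0.0, 1, 0.0, 0.0)

    def test_single_sequence_is_an_error(self):
        with pytest.raises(StatisticsError):
            summarize(panel_of(["ACGT"]))


class TestOracleEquivalence:
    def test_all_six_statistics_match_naive_strings(self, rng):
        """Exact agreement with the character-by-character oracle on 200
        randomized panels (n <= 10, L <= 50)."""
        for _ in range(200):
            seqs = random_panel(rng)
            panel = panel_of(seqs)
            assert seg_sites(panel) == naive.seg_sites(seqs)
            assert haplotypes(panel) == naive.haplotypes(seqs)
            assert watterson(panel) == pytest.approx(naive.watterson(seqs), abs=1e-12)
            assert pairwise_pi(panel) == pytest.approx(naive.pairwise_pi(seqs), abs=1e-12)
            assert allelic_het(panel) == pytest.approx(naive.allelic_het(seqs), abs=1e-12)
            assert nei_het(panel) == pytest.approx(naive.nei_het(seqs), abs=1e-12)

    def test_invariant_bounds(self, rng):
        for _ in range(50):
            seqs = random_panel(rng)
            stats = summarize(panel_of(seqs))
            assert 0 <= stats.S <= stats.L
            assert 1 <= stats.h <= stats.n
            assert 0.0 <= stats.H_A <= 1.0
            assert 0.0 <= stats.H_N <= 1.0
            assert stats.pi <= stats.S or stats.S == 0


class TestPanelProperties:
    def test_permutation_invariance(self, rng):
        seqs = random_panel(rng, max_n=8)
        reference = summarize(panel_of(seqs))
        for _ in range(5):
            rng.shuffle(seqs)
            assert summarize(panel_of(seqs)) == reference

    def test_duplicating_every_sequence(self, rng):
        """Metamorphic: doubling the panel preserves S, h and H_N exactly,
        changes H_A only through the n/(n-1) factor, and changes the mean
        pairwise distance by the exact factor 2(n-1)/(2n-1) (the identical
        duplicate pairs enter the average at distance zero)."""
        seqs = random_panel(rng, max_n=6)
        base, doubled = summarize(panel_of(seqs)), summarize(panel_of(seqs * 2))
        n, n2 = base.n, 2 * base.n
        assert doubled.S == base.S
        assert doubled.h == base.h
        assert doubled.H_N == pytest.approx(base.H_N, abs=1e-12)
        assert doubled.pi == pytest.approx(base.pi * 2 * (n - 1) / (n2 - 1), abs=1e-12)
        biased_base = base.H_A * (n - 1) / n
        assert doubled.H_A * (n2 - 1) / n2 == pytest.approx(biased_base, abs=1e-12)

    def test_appending_an_invariant_site(self, rng):
        """Metamorphic: an extra monomorphic site only rescales H_N by L/(L+1)."""
        seqs = random_panel(rng, max_n=6)
        extended = [s + "A" for s in seqs]
        base, ext = summarize(panel_of(seqs)), summarize(panel_of(extended))
        assert ext.S == base.S
        assert ext.pi == pytest.approx(base.pi)
        assert ext.h == base.h
        assert ext.H_A == pytest.approx(base.H_A)
        assert ext.H_N == pytest.approx(base.H_N * base.L / (base.L + 1))


class TestCollectPanel:
    @pytest.fixture
    def pop(self, four_class_specs, random_mating):
        return found_population(100, four_class_specs, mating_config=random_mating,
                                seed=21)

    def test_panel_sizes_by_class(self, pop):
        assert collect_panel(pop, LocusClass.AUTOSOMAL, 0).n == 200
        assert collect_panel(pop, LocusClass.Y).n == 50
        assert collect_panel(pop, LocusClass.X).n == 150
        assert collect_panel(pop, LocusClass.MT).n == 100

    def test_subsampling_counts_chromosomes_not_individuals(self, pop, rng):
        panel = collect_panel(pop, LocusClass.AUTOSOMAL, 0, sample_size=10, rng=rng)
        assert panel.n == 20
        assert len(set(panel.individual_ids.tolist())) == 10

    def test_empty_y_panel_is_an_error(self, four_class_specs, random_mating):
        pop = found_population(100, four_class_specs, mating_config=random_mating,
                               seed=22)
        # a deme with no males yields no Y carriers at all
        pop.is_female[:] = True
        with pytest.raises(EmptyPanelError):
            collect_panel(pop, LocusClass.Y)
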