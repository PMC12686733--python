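"""Canonical counting, rank tables, Lorenz/Gini."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import kmerlex as kx
from kmerlex.io import Genome, SequenceRecord

dna = st.text(alphabet="ACGT", min_size=1, max_size=40)


def brute_canonical_count(k: int) -> int:
    """Independent oracle: enumerate all 4^k words, collapse by canonicalization."""
    words = ("".join(p) for p in itertools.product("ACGT", repeat=k))
    return len({kx.canonicalize(w) for w in words})


class TestCanonicalize:
    @pytest.mark.parametrize(
        "kmer, expected", [("TTT", "AAA"), ("ACG", "ACG"), ("AT", "AT")]
    )
    def test_examples(self, kmer, expected):
        assert kx.canonicalize(kmer) == expected

    def test_ambiguous_rejected(self):
        with pytest.raises(ValueError):
            kx.canonicalize("ANT")

    @given(dna)
    def test_idempotent_and_minimal(self, s):
        c = kx.canonicalize(s)
        assert kx.canonicalize(c) == c
        assert c == min(s, kx.reverse_complement(s))


class TestExpectedCanonicalCount:
    @pytest.mark.parametrize("k", range(1, 7))
    def test_matches_brute_force_enumeration(self, k):
        assert kx.expected_canonical_count(k) == brute_canonical_count(k)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            kx.expected_canonical_count(0)


class TestCountCanonicalKmers:
    def test_worked_spectrum(self):
        sp = kx.count_canonical_kmers("ACGTACGT", 2)
        assert sp.counts == {"AC": 4, "CG": 2, "TA": 1}
        assert sp.total_tokens == 7

    def test_ambiguous_windows_skipped(self):
        sp = kx.count_canonical_kmers("ACNGT", 2)
        assert sp.counts == {"AC": 2}

    def test_windows_do_not_span_records(self):
        g = Genome(records=(SequenceRecord("a", "AAA"), SequenceRecord("b", "TTT")))
        sp = kx.count_canonical_kmers(g, 3)
        assert sp.counts == {"AAA": 2}

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            kx.count_canonical_kmers("ACGT", 10)

    @given(dna)
    def test_strand_invariance(self, s):
        try:
            fwd = kx.count_canonical_kmers(s, 3).counts
        except ValueError:
            return  # too short for any window
        rev = kx.count_canonical_kmers(kx.reverse_complement(s), 3).counts
        assert fwd == rev

    @given(dna)
    def test_token_conservation(self, s):
        k = 2
        if len(s) < k:
            return
        sp = kx.count_canonical_kmers(s, k)
        assert sp.total_tokens == len(s) - k + 1

    def test_distinct_bound_attained_by_exhaustive_sequence(self):
        # all 256 4-mers concatenated exhaustively covers every canonical 4-mer
        seq = "".join("".join(p) for p in itertools.product("ACGT", repeat=4))
        sp = kx.count_canonical_kmers(seq, 4)
        assert sp.distinct == kx.expected_canonical_count(4)


class TestRankFrequency:
    def test_worked_normalization(self):
        t = kx.to_rank_frequency(kx.count_canonical_kmers("ACGTACGT", 2))
        assert np.allclose(t.frequencies, [4 / 7, 2 / 7, 1 / 7])
        assert list(t.ranks) == [1, 2, 3]

    def test_single_kmer(self):
        t = kx.to_rank_frequency(kx.KmerSpectrum(k=3, counts={"AAA": 5}))
        assert t.frequencies[0] == 1.0

    def test_lexicographic_tie_break(self):
        t = kx.to_rank_frequency(kx.KmerSpectrum(k=2, counts={"AC": 3, "AA": 3}))
        assert t.kmers == ("AA", "AC")

    def test_frequencies_sum_to_one(self, small_genome):
        t = kx.to_rank_frequency(kx.count_canonical_kmers(small_genome, 4))
        assert abs(t.frequencies.sum() - 1.0) < 1e-12

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError):
            kx.to_rank_frequency(kx.KmerSpectrum(k=2, counts={}))


class TestLorenzGini:
    def test_uniform_is_diagonal_with_zero_gini(self):
        t = kx.RankFrequencyTable(counts=np.array([5.0, 5, 5, 5]))
        curve = kx.lorenz_curve(t)
        assert np.allclose(curve.x, curve.y)
        assert kx.gini(curve) == pytest.approx(0.0, abs=1e-12)

    def test_cumulative_shares_by_hand(self):
        t = kx.RankFrequencyTable(counts=np.array([97.0, 1, 1, 1]))
        curve = kx.lorenz_curve(t)
        assert curve.y[3] == pytest.approx(0.03)

    def test_single_kmer_curve(self):
        t = kx.RankFrequencyTable(counts=np.array([5.0]))
        curve = kx.lorenz_curve(t)
        assert np.allclose(curve.x, [0, 1]) and np.allclose(curve.y, [0, 1])

    def test_point_mass_limit(self):
        # one k-mer carries essentially all tokens among m=4: Gini -> 1 - 1/m
        t = kx.RankFrequencyTable(counts=np.array([1e9, 1.0, 1.0, 1.0]))
        assert kx.gini(t) == pytest.approx(0.75, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_trapezoid_agrees_with_mean_absolute_difference(self, seed):
        # independent Gini oracle: sum |xi - xj| / (2 m^2 mu)
        rng = np.random.default_rng(seed)
        counts = np.sort(rng.integers(1, 1000, size=50))[::-1].astype(float)
        x = counts
        mad = np.abs(x[:, None] - x[None, :]).sum() / (2 * x.size**2 * x.mean())
        t = kx.RankFrequencyTable(counts=counts)
        assert kx.gini(t) == pytest.approx(mad, abs=1e-12)

    @given(st.lists(st.integers(1, 10**6), min_size=2, max_size=30), st.integers(2, 100))
    def test_gini_scale_invariant(self, counts, scale):
        counts = np.sort(np.array(counts, dtype=float))[::-1]
        t1 = kx.RankFrequencyTable(counts=counts)
        t2 = kx.RankFrequencyTable(counts=counts * scale)
        assert kx.gini(t1) == pytest.approx(kx.gini(t2), abs=1e-12)

    def test_gini_increases_with_k_on_average(self):
        # statistical property over simulated repeat-rich genomes, in the
        # densely sampled regime (tokens >> possible canonical k-mers)
        wins = 0
        pairs = 0
        for seed in range(20):
            g = kx.synth_hierarchical_repeat_genome(
                n_families=200,
                repeat_total=6000,
                background_length=14_000,
                seed=seed,
            )
            ginis = [
                kx.gini(kx.to_rank_frequency(kx.count_canonical_kmers(g, k)))
                for k in (2, 3, 4, 5)
            ]
            wins += sum(b >= a for a, b in zip(ginis, ginis[1:]))
            pairs += 3
        assert wins / pairs > 0.5
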