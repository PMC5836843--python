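"""Sequence/structure types, Hamming distance, and gain-function bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hamfold as hf
from hamfold.structures import GainContext, InputError


def S(pairs, L, mh=3):
    return hf.SecondaryStructure(frozenset(pairs), L, mh)


class TestTypes:
    def test_sequence_validation_and_t_mapping(self):
        s = hf.RnaSequence("acgt")
        assert s.residues == "ACGU" and s.L == 4
        with pytest.raises(InputError):
            hf.RnaSequence("ACGX")
        with pytest.raises(InputError):
            hf.RnaSequence("")

    def test_structure_invariants(self):
        S({(1, 7), (2, 6)}, 8)  # nested: fine
        with pytest.raises(InputError):
            S({(1, 6), (3, 9)}, 10)  # crossing
        with pytest.raises(InputError):
            S({(1, 6), (6, 10)}, 10)  # position reuse
        with pytest.raises(InputError):
            S({(2, 5)}, 8)  # hairpin too short
        with pytest.raises(InputError):
            S({(0, 5)}, 8)  # out of range

    def test_dotbracket_roundtrip_and_errors(self):
        db = "((...))..(....)"
        s = hf.parse_dotbracket(db)
        assert hf.to_dotbracket(s) == db
        with pytest.raises(InputError, match="column 3"):
            hf.parse_dotbracket("..[..]..")
        with pytest.raises(InputError, match="column"):
            hf.parse_dotbracket("(((....)")
        with pytest.raises(InputError):
            hf.parse_dotbracket("(....)", L=10)


class TestHamming:
    def test_examples(self):
        a = S({(1, 7), (2, 6)}, 8)
        b = S({(1, 6)}, 8)
        assert hf.hamming_distance(a, a) == 0
        assert hf.hamming_distance(S(set(), 8), a) == 2
        assert hf.hamming_distance(a, b) == 3
        assert hf.hamming_distance(b, a) == 3
        with pytest.raises(InputError):
            hf.hamming_distance(a, S(set(), 9))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10**6))
    def test_parity(self, seed):
        seq = hf.random_sequence(14, 0.7, seed)
        a = hf.random_structure(seq, seed=seed + 1)
        b = hf.random_structure(seq, seed=seed + 2)
        d = hf.hamming_distance(a, b)
        assert (d - a.n_pairs - b.n_pairs) % 2 == 0


class TestGains:
    def test_gZ0_examples(self):
        ctx = GainContext(S({(2, 5)}, 6, mh=2))
        assert ctx.gZ0(1, 6) == 1
        assert ctx.gZ0(3, 6) == 0
        ctx2 = GainContext(S({(1, 10), (2, 9), (4, 8)}, 10))
        assert ctx2.gZ0(2, 9) == 2
        assert GainContext(S(set(), 6)).gZ0(1, 6) == 0
        assert ctx.gZ0(4, 3) == 0  # empty interval convention
        with pytest.raises(InputError):
            ctx.gZ0(0, 99)

    def test_g0_cut_examples(self):
        ctx = GainContext(S({(2, 5)}, 6, mh=2))
        assert ctx.g0(1, 6, 3) == 1
        assert ctx.g0(1, 6, 5) == 0
        assert GainContext(S(set(), 6)).g0(1, 6, 3) == 0

    def test_gain_Z_examples(self):
        empty = GainContext(S(set(), 8))
        assert hf.gain_Z(empty, 4, 2, 7) == 1
        ctx = GainContext(S({(1, 10), (2, 9), (4, 8)}, 10))
        # reference contains (2, 9): g4 = gZ0 + 1 - 2 = gZ0 - 1
        assert hf.gain_Z(ctx, 4, 2, 9) == ctx.gZ0(2, 9) - 1
        ctx25 = GainContext(S({(2, 5)}, 6, mh=2))
        assert hf.gain_Z(ctx25, 1, 1, 6) == 1
        with pytest.raises(InputError):
            hf.gain_Z(empty, 9, 1, 8)
        with pytest.raises(InputError):
            hf.gain_Z(empty, 5, 1, 8)  # missing h, l

    def test_gain_W_examples(self):
        empty = GainContext(S(set(), 12))
        assert hf.gain_W(empty, 1, 0, 3, 9, 0) == 0
        assert hf.gain_W(empty, 2, 2, 3, 9, 11) == 1
        only_hl = GainContext(S({(2, 11)}, 12))
        assert hf.gain_W(only_hl, 2, 2, 3, 9, 11) == 0
        with pytest.raises(InputError):
            hf.gain_W(empty, 2, 5, 3, 9, 11)  # bad geometry

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10**6))
    def test_prefix_sums_equal_naive_double_sum(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(6, 16))
        seq = hf.random_sequence(L, 0.7, seed)
        ref = hf.random_structure(seq, seed=seed)
        ctx = GainContext(ref)
        sig = ref.sigma()
        for _ in range(10):
            i = int(rng.integers(1, L + 1))
            j = int(rng.integers(i, L + 1))
            naive = sum(sig[p, q] for p in range(i, j)
                        for q in range(p + 1, j + 1))
            assert ctx.gZ0(i, j) == naive
            if i <= j - 1:
                h = int(rng.integers(i, j))
                naive_cut = sum(sig[p, q] for p in range(i, h + 1)
                                for q in range(h + 1, j + 1))
                assert ctx.g0(i, j, h) == naive_cut

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10**6))
    def test_split_identity(self, seed):
        """gZ0(i,j) = gZ0(i,h) + gZ0(h+1,j) + g0(i,j,h): inside pairs split
        into left, right, and straddling."""
        rng = np.random.default_rng(seed)
        L = int(rng.integers(8, 20))
        ref = hf.random_structure(hf.random_sequence(L, 0.8, seed), seed=seed)
        ctx = GainContext(ref)
        for _ in range(10):
            i = int(rng.integers(1, L))
            j = int(rng.integers(i + 1, L + 1))
            h = int(rng.integers(i, j))
            assert ctx.gZ0(i, j) == (ctx.gZ0(i, h) + ctx.gZ0(h + 1, j)
                                     + ctx.g0(i, j, h))

    def test_gains_never_below_minus_two(self):
        ctx = GainContext(S({(1, 10), (2, 9), (4, 8)}, 10))
        for i in range(1, 10):
            for j in range(i + 4, 11):
                assert hf.gain_Z(ctx, 4, i, j) >= -2
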