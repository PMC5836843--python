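"""Spectral assembly: distributions, decomposed BPPs, 2-D, writers."""

import numpy as np
import pandas as pd
import pytest

import hamfold as hf
from hamfold.spectrum import _validate_real


class TestDistribution:
    def test_open_chain_only(self, toy):
        seq = hf.RnaSequence("AAAAAAAA")
        d = hf.distance_distribution(seq, hf.empty_structure(8), toy)
        assert d.p[0] == pytest.approx(1.0)
        assert d.p[1:].max() < 1e-12

        ref = hf.SecondaryStructure(frozenset({(1, 8), (2, 7)}), 8)
        d = hf.distance_distribution(seq, ref, toy)
        assert d.p[2] == pytest.approx(1.0)

    def test_pair_count_distribution(self, toy):
        # empty reference: p(d) = probability of exactly d base pairs
        seq = hf.random_sequence(12, 0.7, seed=13)
        tab = hf.enumerate_structures(seq, toy)
        by_pairs = np.zeros(13)
        for s, _, w in tab.entries:
            by_pairs[s.n_pairs] += w
        d = hf.distance_distribution(seq, hf.empty_structure(12), toy,
                                     loop_cap=12)
        assert np.abs(d.p - by_pairs / by_pairs.sum()).max() < 1e-12

    def test_normalization_and_conservation(self, turner):
        seq, ref = hf.make_fixture(25, 0.6, seed=21)
        d = hf.distance_distribution(seq, ref, turner)
        assert d.p.sum() == pytest.approx(1.0, abs=1e-9)
        assert d.Z_total == pytest.approx(
            hf.partition_function(seq, turner), rel=1e-9)

    def test_free_energy_view(self, turner):
        seq, ref = hf.make_fixture(15, 0.6, seed=2)
        d = hf.distance_distribution(seq, ref, turner)
        fe = d.free_energy()
        assert np.isfinite(fe[d.p > 0]).all()
        assert np.isinf(fe[d.p == 0]).all()

    def test_determinism(self, turner):
        seq, ref = hf.make_fixture(20, 0.6, seed=5)
        a = hf.distance_distribution(seq, ref, turner)
        b = hf.distance_distribution(seq, ref, turner)
        assert (a.p == b.p).all() and (a.Z_by_d == b.Z_by_d).all()


class TestDecomposedBPP:
    def test_full_range_is_no_decomposition(self, turner):
        seq, ref = hf.make_fixture(30, 0.6, seed=17)
        dec = hf.decomposed_bpp(seq, ref, turner, 0, seq.L)
        assert np.abs(dec.P - hf.bpp_plain(seq, turner)).max() < 1e-9
        assert dec.prob == pytest.approx(1.0, abs=1e-9)

    def test_single_structure_range(self, turner):
        # range [0,0]: only the reference itself
        seq = hf.RnaSequence("GGCGAAAGCGAAACC")
        ref = hf.SecondaryStructure(frozenset({(2, 9), (3, 8)}), seq.L)
        dec = hf.decomposed_bpp(seq, ref, turner, 0, 0)
        sig = np.zeros((seq.L, seq.L))
        for i, j in ref.pairs:
            sig[i - 1, j - 1] = 1.0
        assert np.abs(dec.P - sig).max() < 1e-9
        e = turner.structure_energy(seq, ref)
        assert dec.mass == pytest.approx(turner.boltzmann(e), rel=1e-9)

    def test_range_restriction_matches_enumeration(self, both_models):
        rng = np.random.default_rng(3)
        for seed in (2, 7):
            seq, ref = hf.make_fixture(12, 0.7, seed=seed)
            for m in both_models:
                tab = hf.enumerate_structures(seq, m)
                zd = tab.distance_distribution(ref)
                # distances carrying enough mass for coefficient recovery at
                # double precision (absolute accuracy ~1e-15 * Z)
                support = np.nonzero(zd >= 1e-6 * zd.sum())[0]
                for _ in range(4):
                    a, b = sorted(rng.choice(support, 2))
                    dec = hf.decomposed_bpp(seq, ref, m, int(a), int(b),
                                            loop_cap=12)
                    true = tab.bpp(ref, int(a), int(b))
                    assert np.abs(dec.P - true).max() < 1e-9

    def test_empty_mass_range_raises(self, toy):
        seq = hf.RnaSequence("AAAAAAAA")  # only the open chain exists
        ref = hf.empty_structure(8)
        with pytest.raises(hf.EmptyRangeError, match="no Boltzmann mass"):
            hf.decomposed_bpp(seq, ref, toy, 3, 5)


class TestDistance2D:
    def test_same_reference_concentrates_on_diagonal(self, toy):
        seq, ref = hf.make_fixture(10, 0.7, seed=1)
        d2 = hf.distance_distribution_2d(seq, ref, ref, toy)
        off = d2.p2 - np.diag(np.diag(d2.p2))
        assert np.abs(off).max() < 1e-12

    def test_open_chain_single_cell(self, toy):
        seq = hf.RnaSequence("AAAAAAAAAA")
        r1 = hf.SecondaryStructure(frozenset({(1, 10)}), 10)
        r2 = hf.SecondaryStructure(frozenset({(1, 10), (2, 9)}), 10)
        d2 = hf.distance_distribution_2d(seq, r1, r2, toy)
        assert d2.p2[1, 2] == pytest.approx(1.0)
        assert d2.p2.sum() == pytest.approx(1.0)

    def test_matches_enumeration_and_marginals(self, both_models):
        for seed in (4, 9):
            seq, r1 = hf.make_fixture(10, 0.7, seed=seed)
            r2 = hf.random_structure(seq, seed=seed + 50)
            for m in both_models:
                tab = hf.enumerate_structures(seq, m)
                true = tab.distance_distribution_2d(r1, r2)
                d2 = hf.distance_distribution_2d(seq, r1, r2, m, loop_cap=10)
                assert np.abs(d2.p2 - true / true.sum()).max() < 1e-9
                m1 = hf.distance_distribution(seq, r1, m, loop_cap=10)
                m2 = hf.distance_distribution(seq, r2, m, loop_cap=10)
                assert np.abs(d2.marginal(0) - m1.p).max() < 1e-8
                assert np.abs(d2.marginal(1) - m2.p).max() < 1e-8

    def test_parity_checkerboard(self, toy):
        # cells with (d1 + d2) of the wrong parity are exactly zero
        seq, r1 = hf.make_fixture(10, 0.8, seed=14)
        r2 = hf.random_structure(seq, seed=77)
        d2 = hf.distance_distribution_2d(seq, r1, r2, toy)
        par = (r1.n_pairs + r2.n_pairs) % 2
        d1g, d2g = np.meshgrid(np.arange(11), np.arange(11), indexing="ij")
        bad = (d1g + d2g) % 2 != par
        assert np.all(d2.p2[bad] == 0.0)


class TestGuardsAndWriters:
    def test_negative_coefficient_guard(self):
        ok = _validate_real(np.array([1.0 + 0j, -1e-12 + 0j]), 1.0, "t")
        assert ok[1] == 0.0
        with pytest.raises(hf.AliasingError, match="increase d_max"):
            _validate_real(np.array([1.0 + 0j, -1e-3 + 0j]), 1.0, "t")

    def test_tsv_writers(self, toy, tmp_path):
        seq, ref = hf.make_fixture(10, 0.7, seed=1)
        d = hf.distance_distribution(seq, ref, toy)
        hf.write_distribution_tsv(d, tmp_path / "d.tsv")
        df = pd.read_csv(tmp_path / "d.tsv", sep="\t")
        assert list(df.columns) == ["d", "Z", "p", "neg_RT_log_p"]
        assert df["p"].sum() == pytest.approx(1.0)

        dec = hf.decomposed_bpp(seq, ref, toy, 0, 10)
        hf.write_bpp_tsv(dec.P, tmp_path / "b.tsv")
        df = pd.read_csv(tmp_path / "b.tsv", sep="\t")
        assert list(df.columns) == ["i", "j", "P"]
        assert (df["i"] >= 1).all() and (df["j"] <= 10).all()

        d2 = hf.distance_distribution_2d(seq, ref, ref, toy)
        hf.write_distribution2d_tsv(d2, tmp_path / "d2.tsv")
        df = pd.read_csv(tmp_path / "d2.tsv", sep="\t")
        assert list(df.columns) == ["d1", "d2", "p"]
        assert df["p"].sum() == pytest.approx(1.0)
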