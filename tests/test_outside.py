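"""Outside recursion: x = 1 BPP collapse, spectral oracle, and the
nested-multiloop regression that short random fixtures cannot reach."""

import numpy as np
import pytest

import hamfold as hf
from hamfold.inside import FoldSystem

from conftest import NESTED_ML


def test_x1_bpp_matches_plain_and_enumeration(both_models):
    for seed in range(5):
        seq, ref = hf.make_fixture(12, 0.7, seed=seed)
        L = seq.L
        for m in both_models:
            tab = hf.enumerate_structures(seq, m)
            sysm = FoldSystem(seq, ref, m, loop_cap=L)
            ins = sysm.inside(1.0)
            out = sysm.outside(ins)
            P = (ins.Zb[1:L + 1, 1:L + 1] * out.Wb[1:L + 1, 1:L + 1]).real
            P /= ins.Z[1, L].real
            assert np.abs(P - tab.bpp()).max() < 1e-9
            assert np.abs(P - hf.bpp_plain(seq, m, loop_cap=L)).max() < 1e-9


def test_single_allowed_pair_outside_is_pure_gain_power(toy):
    # only G3-C7 can pair; the exterior is forced open, so Wb = x^{gW1}
    seq = hf.RnaSequence("AAGAAACAA")
    ref = hf.SecondaryStructure(frozenset({(1, 9), (3, 7)}), 9)
    ctx = hf.GainContext(ref)
    x = np.exp(2j * np.pi / 4)
    sysm = FoldSystem(seq, ref, toy)
    out = sysm.outside(sysm.inside(x))
    g = hf.gain_W(ctx, 1, 0, 3, 7, 0)
    assert out.Wb[3, 7] == pytest.approx(x ** g, rel=1e-12)


def test_outside_coefficients_match_enumeration(both_models):
    """The joint mass at inside distance a and outside distance t equals
    Zb(a) * Wb(t), where both coefficient vectors are recovered by DFT and the
    ground truth bins every structure containing (i, j) by the Hamming
    distance split between [i, j] and its outside."""
    for seed in (1, 4):
        seq, ref = hf.make_fixture(12, 0.7, seed=seed)
        L = seq.L
        for m in both_models:
            tab = hf.enumerate_structures(seq, m)
            delta = L + 1
            xs = hf.roots_of_unity(delta)
            sysm = FoldSystem(seq, ref, m, loop_cap=L)
            zbspec = np.zeros((delta, L + 2, L + 2), dtype=complex)
            wbspec = np.zeros((delta, L + 2, L + 2), dtype=complex)
            for r in range(delta):
                ins = sysm.inside(xs[r])
                zbspec[r] = ins.Zb
                wbspec[r] = sysm.outside(ins).Wb
            zb_d = np.fft.fft(zbspec, axis=0).real / delta
            wb_t = np.fft.fft(wbspec, axis=0).real / delta

            checked = 0
            for i in range(1, L + 1):
                for j in range(i + 4, L + 1):
                    if not seq.can_pair(i, j):
                        continue
                    ref_in = {p for p in ref.pairs if i <= p[0] and p[1] <= j}
                    joint = np.zeros((delta, delta))
                    for s, _, w in tab.entries:
                        if (i, j) not in s.pairs:
                            continue
                        s_in = {p for p in s.pairs if i <= p[0] and p[1] <= j}
                        a = len(s_in ^ ref_in)
                        t = len((s.pairs - s_in) ^ (ref.pairs - ref_in))
                        joint[a, t] += w
                    got = np.outer(zb_d[:, i, j], wb_t[:, i, j])
                    assert np.abs(got - joint).max() <= 1e-9 * max(
                        1.0, joint.max()), (i, j, m.name)
                    checked += 1
            assert checked > 0


def test_bpp_plain_properties(toy, turner):
    assert np.all(hf.bpp_plain(hf.RnaSequence("AAAAAAAAAA"), turner) == 0)
    seq = hf.random_sequence(30, 0.6, seed=8)
    P = hf.bpp_plain(seq, turner)
    assert P.min() >= 0 and P.max() <= 1
    tot = P.sum(axis=0) + P.sum(axis=1)  # pairing probability per base
    assert tot.max() <= 1 + 1e-9


def test_expected_pairs_identity(toy):
    seq, ref = hf.make_fixture(13, 0.7, seed=6)
    L = seq.L
    tab = hf.enumerate_structures(seq, toy)
    sysm = FoldSystem(seq, ref, toy, loop_cap=L)
    ins = sysm.inside(1.0)
    out = sysm.outside(ins)
    en = (ins.Zb[1:L + 1, 1:L + 1] * out.Wb[1:L + 1, 1:L + 1]).real.sum()
    en /= ins.Z[1, L].real
    assert en == pytest.approx(tab.expected_pairs(), rel=1e-10)


def test_nested_multiloop_regression(both_models):
    """Branch-in-multiloop outside contexts: every multiloop case of the
    outside recursion must charge the (i,j) branch's own penalty."""
    seq = hf.RnaSequence(NESTED_ML)
    for m in both_models:
        tab = hf.enumerate_structures(seq, m, length_cap=24)
        P = hf.bpp_plain(seq, m, loop_cap=seq.L)
        assert np.abs(P - tab.bpp()).max() < 1e-9


def test_mismatched_inside_outside_rejected(turner):
    seq, ref = hf.make_fixture(10, 0.6, seed=0)
    ins = hf.inside_at_point(seq, ref, turner, 1.0)
    with pytest.raises(hf.InputError):
        hf.outside_at_point(seq, ref, turner, np.exp(2j * np.pi / 3), ins)
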