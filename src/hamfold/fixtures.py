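"""Reproducible random fixtures: sequences and valid reference structures.

The seed touches only fixture generation; the folding pipeline itself is
deterministic.
"""

from __future__ import annotations

import numpy as np

from .structures import DEFAULT_MIN_HAIRPIN, RnaSequence, SecondaryStructure


def random_sequence(length: int, gc_bias: float = 0.5, seed: int = 0,
                    name: str | None = None) -> RnaSequence:
    """Random sequence; ``gc_bias`` is the total probability of G or C
    (0 gives a pure A/U sequence)."""
    rng = np.random.default_rng(seed)
    probs = [(1 - gc_bias) / 2, gc_bias / 2, gc_bias / 2, (1 - gc_bias) / 2]
    letters = rng.choice(list("AGCU"), size=length, p=probs)
    return RnaSequence("".join(letters), name=name or f"fixture_L{length}_s{seed}")


def random_structure(seq: RnaSequence, seed: int = 0, pair_prob: float = 0.6,
                     min_hairpin: int = DEFAULT_MIN_HAIRPIN) -> SecondaryStructure:
    """A random valid structure sampled by interval recursion: non-crossing
    and min-hairpin-respecting by construction, using only allowed pairs."""
    rng = np.random.default_rng(seed)
    pairs: set[tuple[int, int]] = set()

    def sample(i: int, j: int) -> None:
        while j - i >= min_hairpin + 1:
            partners = [l for l in range(i + min_hairpin + 1, j + 1)
                        if seq.can_pair(i, l, min_hairpin)]
            if partners and rng.random() < pair_prob:
                l = int(partners[rng.integers(len(partners))])
                pairs.add((i, l))
                sample(i + 1, l - 1)
                i = l + 1
            else:
                i += 1

    sample(1, seq.L)
    return SecondaryStructure(frozenset(pairs), seq.L, min_hairpin)


def make_fixture(length: int, gc_bias: float = 0.5, seed: int = 0,
                 min_hairpin: int = DEFAULT_MIN_HAIRPIN):
    """(sequence, reference structure) pair, bit-reproducible per seed."""
    seq = random_sequence(length, gc_bias, seed)
    ref = random_structure(seq, seed=seed + 1, min_hairpin=min_hairpin)
    return seq, ref
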