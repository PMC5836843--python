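"""Brute-force enumeration of complete secondary-structure ensembles.

Ground truth for every spectral quantity on short sequences: enumerate every
pseudoknot-free structure, score each with the energy model's loop
decomposition, and reduce the table by simple folds — distribution over
distance, joint distribution over two distances, Boltzmann-averaged pair
indicators restricted to a distance range. A Nussinov-style counting recursion
provides an independent check on the enumeration's completeness.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .energy import EnergyModel
from .structures import (
    DEFAULT_MIN_HAIRPIN,
    InputError,
    RnaSequence,
    SecondaryStructure,
    hamming_distance,
)

ENUM_LENGTH_CAP = 16
ENUM_COUNT_CAP = 500_000


@dataclass
class EnsembleTable:
    """All structures of a sequence with their energies and Boltzmann factors."""

    entries: list[tuple[SecondaryStructure, float, float]]
    sequence: RnaSequence
    model: EnergyModel

    @property
    def Z(self) -> float:
        return float(sum(w for _, _, w in self.entries))

    def distance_distribution(self, ref: SecondaryStructure,
                              d_max: int | None = None) -> np.ndarray:
        """Boltzmann mass per Hamming distance from ``ref`` (index = d)."""
        if d_max is None:
            d_max = self.sequence.L
        out = np.zeros(d_max + 1)
        for s, _, w in self.entries:
            out[hamming_distance(s, ref)] += w
        return out

    def distance_distribution_2d(self, ref1: SecondaryStructure,
                                 ref2: SecondaryStructure,
                                 d1_max: int | None = None,
                                 d2_max: int | None = None) -> np.ndarray:
        L = self.sequence.L
        out = np.zeros(((d1_max or L) + 1, (d2_max or L) + 1))
        for s, _, w in self.entries:
            out[hamming_distance(s, ref1), hamming_distance(s, ref2)] += w
        return out

    def bpp(self, ref: SecondaryStructure | None = None,
            r_min: int = 0, r_max: int | None = None) -> np.ndarray:
        """Boltzmann-averaged pair indicators, optionally restricted to
        structures with Hamming distance to ``ref`` in [r_min, r_max].
        0-based L x L upper triangle."""
        L = self.sequence.L
        if r_max is None:
            r_max = L
        num = np.zeros((L, L))
        mass = 0.0
        for s, _, w in self.entries:
            if ref is not None and not r_min <= hamming_distance(s, ref) <= r_max:
                continue
            mass += w
            for i, j in s.pairs:
                num[i - 1, j - 1] += w
        if mass == 0:
            raise InputError(f"no structures in range [{r_min}, {r_max}]")
        return num / mass

    def expected_pairs(self) -> float:
        return float(sum(w * s.n_pairs for s, _, w in self.entries) / self.Z)


def count_structures(seq: RnaSequence,
                     min_hairpin: int = DEFAULT_MIN_HAIRPIN) -> int:
    """Number of pseudoknot-free structures (interval counting recursion)."""

    @lru_cache(maxsize=None)
    def count(i: int, j: int) -> int:
        if j - i < min_hairpin + 1:
            return 1
        c = count(i + 1, j)
        for l in range(i + min_hairpin + 1, j + 1):
            if seq.can_pair(i, l, min_hairpin):
                c += count(i + 1, l - 1) * (count(l + 1, j) if l < j else 1)
        return c

    n = count(1, seq.L)
    count.cache_clear()
    return n


def enumerate_pair_sets(seq: RnaSequence,
                        min_hairpin: int = DEFAULT_MIN_HAIRPIN,
                        length_cap: int = ENUM_LENGTH_CAP) -> list[frozenset]:
    """Every pseudoknot-free pair set, in deterministic (sorted) order."""
    if seq.L > length_cap:
        raise InputError(
            f"sequence length {seq.L} exceeds enumeration cap {length_cap} "
            f"(~{count_structures(seq, min_hairpin)} structures)")
    n = count_structures(seq, min_hairpin)
    if n > ENUM_COUNT_CAP:
        raise InputError(f"{n} structures exceed enumeration cap {ENUM_COUNT_CAP}")

    @lru_cache(maxsize=None)
    def enum(i: int, j: int) -> list[frozenset]:
        if j - i < min_hairpin + 1:
            return [frozenset()]
        out = list(enum(i + 1, j))
        for l in range(i + min_hairpin + 1, j + 1):
            if not seq.can_pair(i, l, min_hairpin):
                continue
            rights = enum(l + 1, j) if l < j else [frozenset()]
            for left in enum(i + 1, l - 1):
                base = left | {(i, l)}
                for right in rights:
                    out.append(base | right)
        return out

    sets = enum(1, seq.L)
    enum.cache_clear()
    return sorted(sets, key=lambda s: sorted(s))


def enumerate_structures(seq: RnaSequence, model: EnergyModel,
                         min_hairpin: int = DEFAULT_MIN_HAIRPIN,
                         length_cap: int = ENUM_LENGTH_CAP) -> EnsembleTable:
    """The full ensemble table: every structure, its energy, its weight."""
    entries = []
    for pairs in enumerate_pair_sets(seq, min_hairpin, length_cap):
        s = SecondaryStructure(pairs, seq.L, min_hairpin)
        e = model.structure_energy(seq, s)
        entries.append((s, e, model.boltzmann(e)))
    return EnsembleTable(entries, seq, model)
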