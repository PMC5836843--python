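"""Sequence and secondary-structure types, Hamming distance, and gain bookkeeping.

Positions are 1-based and intervals inclusive throughout the public API:
``[i, j]`` means bases i..j of the sequence. A secondary structure is a
pseudoknot-free set of base pairs, equivalently the upper-triangular binary
matrix sigma with sigma[i,j] = 1 iff (i, j) is paired. The Hamming distance
between two structures is the size of the symmetric difference of their pair
sets, i.e. the Hamming distance of the sigma matrices.

The *gain* functions attached to dynamic-programming transitions count how many
reference base pairs become unsatisfiable (or are satisfied) by a transition;
they are the integer exponents of the dummy variable in the distance-classified
partition-function recursions. All of them reduce to two primitives evaluated
in O(1) from a 2-D prefix-sum table over sigma:

* ``gZ0(i, j)`` — number of reference pairs lying entirely within [i, j];
* ``g0(i, j, h)`` — number of reference pairs within [i, j] straddling the cut
  between h and h+1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_MIN_HAIRPIN = 3

#: Canonical pairing alphabet: Watson-Crick plus wobble.
ALLOWED_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)


class InputError(ValueError):
    """Raised on malformed user input (sequences, structures, positions)."""


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence. ``residues`` is over {A, C, G, U}; T is
    mapped to U on construction. ``seq[i]`` with a 1-based i returns a base."""

    residues: str
    name: str = ""

    def __post_init__(self) -> None:
        res = self.residues.upper().replace("T", "U")
        if not res:
            raise InputError("empty sequence")
        bad = set(res) - set("ACGU")
        if bad:
            raise InputError(f"invalid residues {sorted(bad)} in sequence {self.name!r}")
        object.__setattr__(self, "residues", res)

    @property
    def L(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i: int) -> str:
        if not 1 <= i <= self.L:
            raise InputError(f"position {i} outside [1, {self.L}]")
        return self.residues[i - 1]

    def can_pair(self, i: int, j: int, min_hairpin: int = DEFAULT_MIN_HAIRPIN) -> bool:
        """True if bases i and j may pair: allowed letters and j - i > min_hairpin."""
        return j - i >= min_hairpin + 1 and (self[i], self[j]) in ALLOWED_PAIRS


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free set of base pairs on a sequence of length ``L``.

    Invariants enforced at construction: 1 <= i < j <= L, every position in at
    most one pair, no two pairs cross, and j - i >= min_hairpin + 1.
    """

    pairs: frozenset[tuple[int, int]]
    L: int
    min_hairpin: int = DEFAULT_MIN_HAIRPIN

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", frozenset(tuple(p) for p in self.pairs))
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.L):
                raise InputError(f"pair ({i},{j}) outside 1..{self.L}")
            if j - i < self.min_hairpin + 1:
                raise InputError(
                    f"pair ({i},{j}) closes a hairpin shorter than {self.min_hairpin}"
                )
            if i in seen or j in seen:
                raise InputError(f"position reuse in pair ({i},{j})")
            seen.update((i, j))
        ordered = sorted(self.pairs)
        for a in range(len(ordered)):
            i, j = ordered[a]
            for h, l in ordered[a + 1:]:
                if h > j:
                    break
                if i < h < j < l:
                    raise InputError(f"crossing pairs ({i},{j}) and ({h},{l})")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def sigma(self) -> np.ndarray:
        """Upper-triangular 0/1 matrix, shape (L+1, L+1), 1-based indexing."""
        s = np.zeros((self.L + 1, self.L + 1), dtype=np.int32)
        for i, j in self.pairs:
            s[i, j] = 1
        return s

    def partner(self) -> dict[int, int]:
        d: dict[int, int] = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d


def hamming_distance(a: SecondaryStructure, b: SecondaryStructure) -> int:
    """|pairs(a) symmetric-difference pairs(b)|."""
    if a.L != b.L:
        raise InputError(f"length mismatch: {a.L} != {b.L}")
    return len(a.pairs ^ b.pairs)


# ---------------------------------------------------------------------------
# Gain context: prefix-sum table over sigma for O(1) gain evaluation.
# ---------------------------------------------------------------------------

@dataclass
class GainContext:
    """Reference structure plus its inclusion-count prefix table.

    ``cum[i, j]`` = number of reference pairs (p, q) with i <= p < q <= j,
    for 0 <= i, j <= L+1 (out-of-range/empty intervals give 0).
    """

    reference: SecondaryStructure
    cum: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.cum = build_inclusion_table(self.reference)

    @property
    def L(self) -> int:
        return self.reference.L

    def _check(self, *pos: int) -> None:
        for p in pos:
            if not 0 <= p <= self.L + 1:
                raise InputError(f"position {p} outside [0, {self.L + 1}]")

    def gZ0(self, i: int, j: int) -> int:
        """Reference pairs entirely within [i, j]; 0 for empty intervals."""
        self._check(i, j)
        if i >= j:
            return 0
        return int(self.cum[i, j])

    def g0(self, i: int, j: int, h: int) -> int:
        """Reference pairs within [i, j] straddling the cut between h and h+1."""
        self._check(i, j)
        if not i <= h < j:
            raise InputError(f"need i <= h < j, got i={i}, h={h}, j={j}")
        return self.gZ0(i, j) - self.gZ0(i, h) - self.gZ0(h + 1, j)

    def sigma_at(self, i: int, j: int) -> int:
        return 1 if (i, j) in self.reference.pairs else 0


def build_inclusion_table(ref: SecondaryStructure) -> np.ndarray:
    """2-D table T[i, j] = #{(p, q) in ref : i <= p < q <= j}, shape (L+2, L+2).

    Recurrence: T[i, j] = T[i+1, j] + T[i, j-1] - T[i+1, j-1] + sigma[i, j].
    """
    L = ref.L
    T = np.zeros((L + 2, L + 2), dtype=np.int64)
    sig = {(i, j) for i, j in ref.pairs}
    for i in range(L, 0, -1):
        for j in range(i + 1, L + 1):
            T[i, j] = T[i + 1, j] + T[i, j - 1] - T[i + 1, j - 1] + ((i, j) in sig)
    return T


# ---------------------------------------------------------------------------
# The gain functions as printed in the method's derivation. g^Z_4..6 carry an
# indicator of the pair being closed by the transition (sigma_{i,j}).
# ---------------------------------------------------------------------------

def gain_Z(ctx: GainContext, which: int, i: int, j: int,
           h: int | None = None, l: int | None = None) -> int:
    """Inside-recursion distance gain g^Z_1..g^Z_8 for the transition geometry
    (i, j[, h[, l]]). Returns the integer exponent of the dummy variable."""
    if which == 1:
        return ctx.gZ0(i, j)
    if which == 2:
        _need(h is not None, "g^Z_2 needs h")
        return ctx.g0(i, j, h)
    if which == 3:
        _need(h is not None, "g^Z_3 needs h")
        return ctx.g0(i, j, h + 1) + ctx.gZ0(h + 1, j)
    if which == 4:
        return ctx.gZ0(i, j) + 1 - 2 * ctx.sigma_at(i, j)
    if which == 5:
        _need(h is not None and l is not None, "g^Z_5 needs h and l")
        return ctx.gZ0(i, j) - ctx.gZ0(h, l) + 1 - 2 * ctx.sigma_at(i, j)
    if which == 6:
        _need(h is not None, "g^Z_6 needs h")
        return (ctx.gZ0(i, j) - ctx.gZ0(i + 1, h - 1) - ctx.gZ0(h, j - 1)
                + 1 - 2 * ctx.sigma_at(i, j))
    if which == 7:
        _need(h is not None, "g^Z_7 needs h")
        return ctx.gZ0(i, h - 1) + ctx.g0(i, j, h)
    if which == 8:
        _need(h is not None, "g^Z_8 needs h")
        return ctx.g0(i, j, h - 1)
    raise InputError(f"gain_Z index must be 1..8, got {which}")


def gain_W(ctx: GainContext, which: int, h: int, i: int, j: int, l: int) -> int:
    """Outside-recursion distance gain g^W_1..g^W_5.

    g^W_1 depends on (i, j) only (pair external to any other pair); g^W_2..5
    need the enclosing pair (h, l) with h < i < j < l.
    """
    L = ctx.L
    if which == 1:
        return (ctx.gZ0(1, L) - ctx.gZ0(i, j)
                - ctx.gZ0(1, i - 1) - ctx.gZ0(j + 1, L))
    if not h < i < j < l:
        raise InputError(f"need h < i < j < l, got ({h},{i},{j},{l})")
    gw2 = ctx.gZ0(h, l) - ctx.gZ0(i, j) + 1 - 2 * ctx.sigma_at(h, l)
    if which == 2:
        return gw2
    if which == 3:
        return gw2 - ctx.gZ0(h + 1, i - 1)
    if which == 4:
        return gw2 - ctx.gZ0(j + 1, l - 1)
    if which == 5:
        return gw2 - ctx.gZ0(h + 1, i - 1) - ctx.gZ0(j + 1, l - 1)
    raise InputError(f"gain_W index must be 1..5, got {which}")


def _need(cond: bool, msg: str) -> None:
    if not cond:
        raise InputError(msg)


# ---------------------------------------------------------------------------
# Dot-bracket and FASTA IO.
# ---------------------------------------------------------------------------

def parse_dotbracket(s: str, L: int | None = None,
                     min_hairpin: int = DEFAULT_MIN_HAIRPIN) -> SecondaryStructure:
    """Parse a pseudoknot-free dot-bracket string using '.', '(' and ')' only.

    Raises :class:`InputError` naming the offending 1-based column on any other
    character or on unbalanced brackets.
    """
    s = s.strip()
    if L is not None and len(s) != L:
        raise InputError(f"dot-bracket length {len(s)} != sequence length {L}")
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for col, ch in enumerate(s, start=1):
        if ch == "(":
            stack.append(col)
        elif ch == ")":
            if not stack:
                raise InputError(f"unbalanced ')' at column {col}")
            pairs.add((stack.pop(), col))
        elif ch != ".":
            raise InputError(f"invalid character {ch!r} at column {col}")
    if stack:
        raise InputError(f"unbalanced '(' at column {stack[-1]}")
    return SecondaryStructure(frozenset(pairs), len(s), min_hairpin)


def to_dotbracket(s: SecondaryStructure) -> str:
    out = ["."] * s.L
    for i, j in s.pairs:
        out[i - 1] = "("
        out[j - 1] = ")"
    return "".join(out)


def read_fasta(path) -> RnaSequence:
    """Read a single-record FASTA file (the main pipeline enforces one record)."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise InputError(f"expected exactly one FASTA record, found {len(records)}")
    rec = records[0]
    return RnaSequence(str(rec.seq), name=rec.id)
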