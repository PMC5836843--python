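"""Outside recursion over Hamming distance, and a plain McCaskill reference.

``outside_at_point`` is the distance-classified outside algorithm (the SCFG
outside analogue of the inside recursion), run from long spans to short ones.
``bpp_plain`` is an independent, real-valued McCaskill base-pairing-probability
implementation with no distance bookkeeping at all: it recomputes every loop
weight directly from the energy model and serves both as the x = 1 oracle for
the spectral pipeline and as the source of undecomposed reference structures.
"""

from __future__ import annotations

import numpy as np

from .energy import EnergyModel, pair_code
from .inside import (
    DEFAULT_LOOP_CAP,
    FoldSystem,
    InsideMatrices,
    OutsideMatrix,
)
from .structures import (
    DEFAULT_MIN_HAIRPIN,
    InputError,
    RnaSequence,
    SecondaryStructure,
)


def outside_at_point(seq: RnaSequence, ref: SecondaryStructure,
                     model: EnergyModel, x: complex,
                     inside: InsideMatrices, **kw) -> OutsideMatrix:
    """W^b at the evaluation point of ``inside`` (which must match ``x``)."""
    if complex(x) != complex(inside.x):
        raise InputError("evaluation point does not match the inside matrices")
    sysm = FoldSystem(seq, ref, model, **kw)
    return sysm.outside(inside)


def bpp_plain(seq: RnaSequence, model: EnergyModel,
              min_hairpin: int = DEFAULT_MIN_HAIRPIN,
              loop_cap: int = DEFAULT_LOOP_CAP) -> np.ndarray:
    """Classic McCaskill base-pairing probabilities, 0-based L x L array.

    P[i-1, j-1] (i < j, 1-based) is the Boltzmann probability that (i, j) is
    paired. Row sums never exceed 1.
    """
    L = seq.L
    bz = model.boltzmann
    code = np.full((L + 2, L + 2), -1, dtype=int)
    for i in range(1, L + 1):
        for j in range(i + min_hairpin + 1, L + 1):
            code[i, j] = pair_code(seq[i], seq[j])

    wml_close = bz(model.ml_a + model.ml_b)
    wml_branch = bz(model.ml_b)
    wu = bz(model.ml_c)

    Z = np.zeros((L + 2, L + 2))
    Z1 = np.zeros((L + 2, L + 2))
    Zb = np.zeros((L + 2, L + 2))
    Zm = np.zeros((L + 2, L + 2))
    Zm1 = np.zeros((L + 2, L + 2))

    def two(i, j, h, l):
        return bz(model.interior_energy(seq, i, j, h, l))

    for span in range(1, L + 1):
        for i in range(1, L - span + 2):
            j = i + span - 1
            if span >= min_hairpin + 2 and code[i, j] >= 0:
                acc = bz(model.hairpin_energy(seq, i, j))
                for h in range(i + 1, min(j - min_hairpin - 1, i + loop_cap + 2)):
                    n1 = h - i - 1
                    for l in range(max(h + min_hairpin + 1, j - 1 - (loop_cap - n1)), j):
                        if code[h, l] >= 0 and Zb[h, l] != 0:
                            acc += two(i, j, h, l) * Zb[h, l]
                for h in range(i + min_hairpin + 3, j - min_hairpin - 1):
                    acc += wml_close * Zm[i + 1, h - 1] * Zm1[h, j - 1]
                Zb[i, j] = acc
            tail = 1.0
            for l in range(j, i + min_hairpin, -1):
                if Zb[i, l] != 0:
                    Z1[i, j] += Zb[i, l]
                    Zm1[i, j] += Zb[i, l] * wml_branch * tail
                tail *= wu
            lead = 1.0
            for h in range(i, j - min_hairpin):
                if Zm1[h, j] != 0:
                    left = lead + (Zm[i, h - 1] if h > i else 0.0)
                    Zm[i, j] += left * Zm1[h, j]
                if Z1[h, j] != 0:
                    Z[i, j] += (Z[i, h - 1] if h > i else 1.0) * Z1[h, j]
                lead *= wu
            Z[i, j] += 1.0

    Wb = np.zeros((L + 2, L + 2))
    M = np.full((L + 2, L + 2), np.nan)
    N = np.full((L + 2, L + 2), np.nan)
    for span in range(L, min_hairpin + 1, -1):
        for i in range(1, L - span + 2):
            j = i + span - 1
            if code[i, j] < 0:
                continue
            acc = (Z[1, i - 1] if i > 1 else 1.0) * (Z[j + 1, L] if j < L else 1.0)
            for h in range(max(1, i - loop_cap - 1), i):
                n1 = i - h - 1
                for l in range(j + 1, min(L, j + 1 + (loop_cap - n1)) + 1):
                    if code[h, l] >= 0 and Wb[h, l] != 0:
                        acc += Wb[h, l] * two(h, l, i, j)
            for l in range(j + 1, L + 1):
                if np.isnan(M[i, l]):
                    # enclosing closure's a + b, plus b for the (i,j) branch
                    M[i, l] = wml_close * wml_branch * sum(
                        Wb[h, l] * Zm[h + 1, i - 1]
                        for h in range(1, i - 1) if code[h, l] >= 0)
            for h in range(1, i):
                if np.isnan(N[j, h]):
                    N[j, h] = wml_close * wml_branch * sum(
                        Wb[h, l] * Zm[j + 1, l - 1]
                        for l in range(j + 2, L + 1) if code[h, l] >= 0)
            tail = 1.0
            for l in range(j + 1, L + 1):
                acc += M[i, l] * tail
                if l >= j + 2:
                    acc += M[i, l] * Zm[j + 1, l - 1]
                tail *= wu
            lead = 1.0
            for h in range(i - 1, 0, -1):
                acc += N[j, h] * lead
                lead *= wu
            Wb[i, j] = acc

    P = np.zeros((L, L))
    Ztot = Z[1, L]
    for i in range(1, L + 1):
        for j in range(i + 1, L + 1):
            if code[i, j] >= 0:
                P[i - 1, j - 1] = Zb[i, j] * Wb[i, j] / Ztot
    return P


def expected_pairs_plain(seq: RnaSequence, model: EnergyModel, **kw) -> float:
    """Ensemble-average number of base pairs, from the plain BPP matrix."""
    return float(bpp_plain(seq, model, **kw).sum())
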