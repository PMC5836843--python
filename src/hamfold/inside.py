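"""Inside recursion over Hamming distance, evaluated at points on the unit circle.

At ``x = 1`` every distance gain collapses (``1**g = 1``) and the recursion is
exactly McCaskill's partition function. At ``x = exp(2 pi i r / Delta)`` the
matrices hold the distance-classified polynomials evaluated at that root of
unity; the spectrum module recovers the coefficients by inverse DFT.

A second reference structure may be supplied together with a second evaluation
point ``y``; gains against it become exponents of ``y``, which is how the 2-D
distribution over distances to two references is computed.
"""

from __future__ import annotations

import cmath
from dataclasses import dataclass

import numpy as np

from ._kernels import inside_kernel, outside_kernel
from .energy import EnergyModel, pair_code
from .structures import (
    DEFAULT_MIN_HAIRPIN,
    GainContext,
    InputError,
    RnaSequence,
    SecondaryStructure,
)

DEFAULT_LOOP_CAP = 30


def empty_structure(L: int, min_hairpin: int = DEFAULT_MIN_HAIRPIN) -> SecondaryStructure:
    return SecondaryStructure(frozenset(), L, min_hairpin)


@dataclass
class InsideMatrices:
    """The five inside matrices at one (pair of) evaluation point(s).

    Arrays are (L+2) x (L+2) complex, 1-based; ``scale`` is the per-base
    rescaling constant: stored entries carry a factor scale**(bases covered).
    """

    Z: np.ndarray
    Z1: np.ndarray
    Zb: np.ndarray
    Zm: np.ndarray
    Zm1: np.ndarray
    x: complex
    y: complex
    scale: float
    L: int

    @property
    def Z_total(self) -> complex:
        """Z~_{1,L} at the evaluation point, unscaled."""
        return self.Z[1, self.L] / self.scale ** self.L


@dataclass
class OutsideMatrix:
    """Outside matrix W^b at the same evaluation point(s) as its inside."""

    Wb: np.ndarray
    x: complex
    y: complex
    scale: float
    L: int


class FoldSystem:
    """Precomputed Boltzmann-weight tables and gain tables for one problem.

    Building the tables once and evaluating at many roots of unity is what the
    spectrum module does; each evaluation point is independent (the DP at
    different points may run in any order or in parallel with identical
    results).
    """

    def __init__(self, seq: RnaSequence, ref: SecondaryStructure,
                 model: EnergyModel, ref2: SecondaryStructure | None = None,
                 min_hairpin: int = DEFAULT_MIN_HAIRPIN,
                 loop_cap: int = DEFAULT_LOOP_CAP, scale: float = 1.0):
        L = seq.L
        if ref.L != L:
            raise InputError(f"reference length {ref.L} != sequence length {L}")
        if ref2 is not None and ref2.L != L:
            raise InputError(f"second reference length {ref2.L} != sequence length {L}")
        if scale <= 0:
            raise InputError("scale must be positive")
        self.seq, self.model, self.L = seq, model, L
        self.ref = ref
        self.ref2 = ref2 if ref2 is not None else empty_structure(L, min_hairpin)
        self.min_hairpin = int(min_hairpin)
        self.loop_cap = int(loop_cap)
        self.scale = float(scale)

        ctx1, ctx2 = GainContext(ref), GainContext(self.ref2)
        self.ctx1, self.ctx2 = ctx1, ctx2
        self.cum1 = np.ascontiguousarray(ctx1.cum)
        self.cum2 = np.ascontiguousarray(ctx2.cum)
        sig = np.zeros((L + 2, L + 2), dtype=np.int64)
        for i, j in ref.pairs:
            sig[i, j] = 1
        self.sig1 = sig
        sig2 = np.zeros((L + 2, L + 2), dtype=np.int64)
        for i, j in self.ref2.pairs:
            sig2[i, j] = 1
        self.sig2 = sig2

        m = model
        bz = m.boltzmann
        self.pcode = np.full((L + 2, L + 2), -1, dtype=np.int64)
        self.whp = np.zeros((L + 2, L + 2), dtype=np.float64)
        for i in range(1, L + 1):
            for j in range(i + self.min_hairpin + 1, L + 1):
                c = pair_code(seq[i], seq[j])
                if c >= 0:
                    self.pcode[i, j] = c
                    self.whp[i, j] = bz(m.hairpin_energy(seq, i, j))
        cap = self.loop_cap
        self.wstack = np.array([[bz(m.stack[a, b]) for b in range(6)]
                                for a in range(6)])
        self.wbulge = np.array([bz(m._init_energy(m.bulge_init, n)) if n else 0.0
                                for n in range(cap + 1)])
        self.wintl = np.array(
            [bz(m._init_energy(m.interior_init, n)) if n >= 2 else 0.0
             for n in range(cap + 1)])
        self.wasym = np.array(
            [bz(min(m.asym_per_nt * k, m.asym_max)) for k in range(cap + 1)])
        self.wterm = np.array([bz(m._terminal(c)) for c in range(6)])
        self.wml_close = bz(m.ml_a + m.ml_b)
        self.wml_branch = bz(m.ml_b)
        self.wml_unp = bz(m.ml_c)
        self.spow = self.scale ** np.arange(L + 2, dtype=np.float64)
        self._off = L + 2

    def _xpow(self, x: complex) -> np.ndarray:
        off = self._off
        return np.asarray(x, dtype=np.complex128) ** np.arange(-off, 2 * self.L + 3)

    def inside(self, x: complex, y: complex = 1.0) -> InsideMatrices:
        _check_unit(x)
        _check_unit(y)
        Z, Z1, Zb, Zm, Zm1 = inside_kernel(
            self.L, self.pcode, self.sig1, self.sig2, self.cum1, self.cum2,
            self.whp, self.wstack, self.wbulge, self.wintl, self.wasym,
            self.wterm, self.wml_close, self.wml_branch, self.wml_unp,
            self._xpow(x), self._off, self._xpow(y), self._off,
            self.spow, self.min_hairpin, self.loop_cap)
        return InsideMatrices(Z, Z1, Zb, Zm, Zm1, complex(x), complex(y),
                              self.scale, self.L)

    def outside(self, inside: InsideMatrices) -> OutsideMatrix:
        if inside.L != self.L or inside.scale != self.scale:
            raise InputError("inside matrices do not match this system")
        Wb = outside_kernel(
            self.L, self.pcode, self.sig1, self.sig2, self.cum1, self.cum2,
            self.wstack, self.wbulge, self.wintl, self.wasym, self.wterm,
            self.wml_close, self.wml_branch, self.wml_unp,
            self._xpow(inside.x), self._off, self._xpow(inside.y), self._off,
            self.spow, self.min_hairpin, self.loop_cap,
            inside.Z, inside.Zm, inside.Zb)
        return OutsideMatrix(Wb, inside.x, inside.y, self.scale, self.L)


def _check_unit(x: complex) -> None:
    if abs(abs(complex(x)) - 1.0) > 1e-12:
        raise InputError(f"evaluation point {x} is off the unit circle")


def inside_at_point(seq: RnaSequence, ref: SecondaryStructure, model: EnergyModel,
                    x: complex, **kw) -> InsideMatrices:
    """Evaluate the five inside matrices at one point |x| = 1."""
    y = kw.pop("y", 1.0)
    ref2 = kw.pop("ref2", None)
    return FoldSystem(seq, ref, model, ref2=ref2, **kw).inside(x, y)


def partition_function(seq: RnaSequence, model: EnergyModel, **kw) -> float:
    """Classic McCaskill partition function (the recursion at x = 1)."""
    ref = empty_structure(seq.L, kw.get("min_hairpin", DEFAULT_MIN_HAIRPIN))
    z = inside_at_point(seq, ref, model, 1.0, **kw).Z_total.real
    if not np.isfinite(z):
        raise InputError(
            "partition function overflowed; rerun with a smaller `scale` "
            "(per-base rescaling constant < 1)")
    return float(z)


def roots_of_unity(delta: int) -> np.ndarray:
    """The Delta evaluation points exp(2 pi i r / Delta), r = 0..Delta-1."""
    return np.exp(2j * cmath.pi * np.arange(delta) / delta)
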