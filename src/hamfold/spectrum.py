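"""Spectral assembly: evaluate the DPs at roots of unity, invert the DFT.

The distance-classified partition function is a polynomial in a dummy variable
whose coefficient at degree d is the Boltzmann mass at Hamming distance d.
Evaluating the inside (and outside) recursions at the Delta = d_max + 1 roots
of unity and applying the inverse DFT recovers the coefficients exactly —
no polynomial convolution is ever materialized: the product Zb * Wb needed for
the decomposed base-pairing probabilities is a plain complex product at each
evaluation point.

Coefficients are real by construction, so only the first half of the spectrum
is computed and the rest filled by conjugate symmetry. Tiny negative
coefficients (roundoff) are clamped to zero; larger negatives raise
:class:`AliasingError` rather than being silently hidden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .energy import EnergyModel
from .inside import DEFAULT_LOOP_CAP, FoldSystem, roots_of_unity
from .structures import (
    DEFAULT_MIN_HAIRPIN,
    InputError,
    RnaSequence,
    SecondaryStructure,
)

log = logging.getLogger(__name__)

#: negative coefficients below -NEG_TOL * total are an error, not roundoff
NEG_TOL = 1e-8
#: coefficients within ZERO_TOL * total of zero are set to exactly zero
#: (below double-precision recovery accuracy; keeps unreachable distance
#: cells exactly empty)
ZERO_TOL = 1e-13


class AliasingError(RuntimeError):
    """A recovered coefficient is too negative to be roundoff: the transform
    width Delta was smaller than the true distance support. Increase d_max."""


class EmptyRangeError(ValueError):
    """A distance range holding no Boltzmann mass (a vacuous peak)."""


@dataclass
class DistanceDistribution:
    """p(d) and the Boltzmann mass per Hamming distance d = 0..d_max."""

    p: np.ndarray
    Z_by_d: np.ndarray
    d_min: int
    d_max: int
    reference: SecondaryStructure
    RT: float

    @property
    def Z_total(self) -> float:
        return float(self.Z_by_d.sum())

    def free_energy(self) -> np.ndarray:
        """-RT log p(d); +inf where p(d) = 0."""
        with np.errstate(divide="ignore"):
            return -self.RT * np.log(self.p)

    def distances(self) -> np.ndarray:
        return np.arange(self.d_min, self.d_max + 1)


@dataclass
class DecomposedBPP:
    """Base-pairing probabilities restricted to d in [r_min, r_max].

    ``P`` is 0-based L x L (upper triangle); ``mass`` is the Boltzmann mass of
    the range, ``prob`` its share of the full partition function.
    """

    P: np.ndarray
    r_min: int
    r_max: int
    mass: float
    prob: float
    reference: SecondaryStructure


@dataclass
class Distance2D:
    """Joint mass/probability over distances to two reference structures."""

    p2: np.ndarray
    Z2: np.ndarray
    references: tuple[SecondaryStructure, SecondaryStructure]
    RT: float

    def marginal(self, axis: int) -> np.ndarray:
        return self.p2.sum(axis=1 - axis)


# ---------------------------------------------------------------------------

def _coeffs_from_spectrum(spec: np.ndarray, axis: int = 0) -> np.ndarray:
    """Coefficient recovery: (1/Delta) sum_r exp(-2 pi i r d / Delta) * spec[r].

    The evaluation points use the +2 pi i kernel, so recovery is numpy's
    forward FFT divided by Delta.
    """
    return np.fft.fft(spec, axis=axis) / spec.shape[axis]


def _validate_real(coeffs: np.ndarray, total: float, what: str) -> np.ndarray:
    re = coeffs.real.copy()
    floor = -NEG_TOL * max(total, 1.0)
    if re.min() < floor:
        raise AliasingError(
            f"{what}: coefficient {re.min():.3e} below tolerance {floor:.3e}; "
            "the transform width was too small — increase d_max")
    re[re < ZERO_TOL * max(total, 1.0)] = 0.0
    return re


def _half_spectrum(delta: int):
    """Indices r = 0..delta//2; the rest follows by conjugate symmetry."""
    return range(delta // 2 + 1)


def _mirror(spec: np.ndarray, delta: int, axis: int = 0) -> None:
    for r in range(delta // 2 + 1, delta):
        src = np.take(spec, delta - r, axis=axis)
        idx = [slice(None)] * spec.ndim
        idx[axis] = r
        spec[tuple(idx)] = np.conj(src)


def distance_distribution(seq: RnaSequence, ref: SecondaryStructure,
                          model: EnergyModel, d_min: int = 0,
                          d_max: int | None = None,
                          min_hairpin: int = DEFAULT_MIN_HAIRPIN,
                          loop_cap: int = DEFAULT_LOOP_CAP,
                          scale: float = 1.0) -> DistanceDistribution:
    """p(d, sigma) = Z(d, sigma) / Z for d = d_min..d_max.

    The transform is always taken over [0, d_max] (Delta = d_max + 1 roots of
    unity) and sliced, avoiding any spectrum-shift ambiguity; probabilities are
    normalized by the full partition function.
    """
    if d_max is None:
        d_max = seq.L
    if not 0 <= d_min <= d_max:
        raise InputError(f"need 0 <= d_min <= d_max, got [{d_min}, {d_max}]")
    sysm = FoldSystem(seq, ref, model, min_hairpin=min_hairpin,
                      loop_cap=loop_cap, scale=scale)
    delta = d_max + 1
    xs = roots_of_unity(delta)
    spec = np.empty(delta, dtype=np.complex128)
    for r in _half_spectrum(delta):
        spec[r] = sysm.inside(xs[r]).Z_total
    _mirror(spec, delta)
    log.info("1D transform: L=%d Delta=%d model=%s/%s", seq.L, delta,
             model.name, model.version)
    Zd = _validate_real(_coeffs_from_spectrum(spec), abs(spec[0]), "Z(d)")
    total = Zd.sum()
    dist = DistanceDistribution(
        p=(Zd / total)[d_min:], Z_by_d=Zd[d_min:], d_min=d_min, d_max=d_max,
        reference=ref, RT=model.R * model.temperature)
    return dist


def decomposed_bpp(seq: RnaSequence, ref: SecondaryStructure,
                   model: EnergyModel, r_min: int, r_max: int,
                   d_max: int | None = None,
                   min_hairpin: int = DEFAULT_MIN_HAIRPIN,
                   loop_cap: int = DEFAULT_LOOP_CAP,
                   scale: float = 1.0) -> DecomposedBPP:
    """BPP matrix restricted to Hamming distances in [r_min, r_max].

    The numerator polynomial Zb_ij * Wb_ij is never convolved: its spectrum is
    the pointwise product of the inside and outside spectra, inverted by DFT,
    summed over the (inclusive) range and divided by the range's mass.
    """
    L = seq.L
    if d_max is None:
        d_max = L
    if not 0 <= r_min <= r_max <= d_max:
        raise InputError(
            f"range [{r_min}, {r_max}] must sit within [0, {d_max}]")
    sysm = FoldSystem(seq, ref, model, min_hairpin=min_hairpin,
                      loop_cap=loop_cap, scale=scale)
    delta = d_max + 1
    xs = roots_of_unity(delta)
    zspec = np.empty(delta, dtype=np.complex128)
    nspec = np.empty((delta, L, L), dtype=np.complex128)
    for r in _half_spectrum(delta):
        ins = sysm.inside(xs[r])
        out = sysm.outside(ins)
        zspec[r] = ins.Z_total
        nspec[r] = (ins.Zb[1:L + 1, 1:L + 1] * out.Wb[1:L + 1, 1:L + 1]
                    / scale ** L)
    _mirror(zspec, delta)
    _mirror(nspec, delta)

    Zd = _validate_real(_coeffs_from_spectrum(zspec), abs(zspec[0]), "Z(d)")
    Nd = _coeffs_from_spectrum(nspec, axis=0)
    mass = float(Zd[r_min:r_max + 1].sum())
    total = float(Zd.sum())
    if mass <= ZERO_TOL * total:
        raise EmptyRangeError(
            f"no Boltzmann mass in range [{r_min}, {r_max}]")
    num = _validate_real(Nd[r_min:r_max + 1].sum(axis=0), total,
                         "Zb*Wb coefficients")
    P = num / mass
    np.clip(P, 0.0, 1.0, out=P)
    P[P > 1.0 - 1e-12] = 1.0  # within coefficient-recovery precision of 1
    return DecomposedBPP(P=P, r_min=r_min, r_max=r_max, mass=mass,
                         prob=mass / total, reference=ref)


def distance_distribution_2d(seq: RnaSequence, ref1: SecondaryStructure,
                             ref2: SecondaryStructure, model: EnergyModel,
                             d1_max: int | None = None,
                             d2_max: int | None = None,
                             min_hairpin: int = DEFAULT_MIN_HAIRPIN,
                             loop_cap: int = DEFAULT_LOOP_CAP,
                             scale: float = 1.0) -> Distance2D:
    """Joint distribution over (d1, d2) = distances to two references.

    Cost is Delta1 * Delta2 inside evaluations (conjugate symmetry halves one
    axis); intended for moderate lengths — the 1D transform is the workhorse.
    """
    L = seq.L
    if d1_max is None:
        d1_max = L
    if d2_max is None:
        d2_max = L
    sysm = FoldSystem(seq, ref1, model, ref2=ref2, min_hairpin=min_hairpin,
                      loop_cap=loop_cap, scale=scale)
    delta1, delta2 = d1_max + 1, d2_max + 1
    xs, ys = roots_of_unity(delta1), roots_of_unity(delta2)
    spec = np.empty((delta1, delta2), dtype=np.complex128)
    for s in _half_spectrum(delta2):
        for r in range(delta1):
            spec[r, s] = sysm.inside(xs[r], ys[s]).Z_total
    # conjugate symmetry of the real 2-D coefficient array:
    # spec[-r mod, -s mod] = conj(spec[r, s])
    for s in range(delta2 // 2 + 1, delta2):
        for r in range(delta1):
            spec[r, s] = np.conj(spec[(delta1 - r) % delta1, delta2 - s])
    Z2 = np.fft.fft2(spec) / (delta1 * delta2)
    Z2 = _validate_real(Z2, abs(spec[0, 0]), "Z(d1,d2)")
    total = Z2.sum()
    return Distance2D(p2=Z2 / total, Z2=Z2, references=(ref1, ref2),
                      RT=model.R * model.temperature)


# ---------------------------------------------------------------------------
# TSV writers (1-based positions; fixed headers)
# ---------------------------------------------------------------------------

def write_distribution_tsv(dist: DistanceDistribution, path) -> None:
    fe = dist.free_energy()
    pd.DataFrame({
        "d": dist.distances(), "Z": dist.Z_by_d, "p": dist.p,
        "neg_RT_log_p": fe,
    }).to_csv(path, sep="\t", index=False)


def write_distribution2d_tsv(d2: Distance2D, path) -> None:
    n1, n2 = d2.p2.shape
    d1, d2i = np.meshgrid(np.arange(n1), np.arange(n2), indexing="ij")
    pd.DataFrame({
        "d1": d1.ravel(), "d2": d2i.ravel(), "p": d2.p2.ravel(),
    }).to_csv(path, sep="\t", index=False)


def write_bpp_tsv(P: np.ndarray, path, dense: bool = False,
                  threshold: float = 0.0) -> None:
    """Long-format (i, j, P) with 1-based positions; by default only entries
    above ``threshold`` are written, ``dense`` writes the full upper triangle."""
    L = P.shape[0]
    rows = [(i + 1, j + 1, P[i, j])
            for i in range(L) for j in range(i + 1, L)
            if dense or P[i, j] > threshold]
    pd.DataFrame(rows, columns=["i", "j", "P"]).to_csv(
        path, sep="\t", index=False)
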