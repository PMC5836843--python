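"""Posterior decoding of BPP matrices and peak-range detection.

The gamma-centroid estimator is the pseudoknot-free structure maximizing
sum over predicted pairs of ((gamma + 1) P_ij - 1); only pairs with
P_ij > 1/(gamma + 1) can contribute positively, so increasing gamma admits
more (less certain) pairs. Decoding is a Nussinov-style interval DP.

Peak ranges on a 1-D distance distribution follow the rule: keep only
distances with p(d) above the Boltzmann threshold exp(Q / RT), then split the
surviving support at every strict local minimum d' (p(d'-1) > p(d') < p(d'+1));
adjacent ranges share the split point, and the shared bin is counted in both
masses. Plateaus are not split points (the rule uses strict inequalities).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .energy import GAS_CONSTANT
from .spectrum import DistanceDistribution
from .structures import DEFAULT_MIN_HAIRPIN, InputError, SecondaryStructure

log = logging.getLogger(__name__)


@dataclass
class PeakRange:
    """A candidate structural cluster: distances r_min..r_max inclusive."""

    r_min: int
    r_max: int
    mass: float
    representative: SecondaryStructure | None = None


def gamma_centroid(P: np.ndarray, gamma: float = 1.0,
                   min_hairpin: int = DEFAULT_MIN_HAIRPIN) -> SecondaryStructure:
    """Maximum expected gain structure for a 0-based L x L BPP matrix.

    Deterministic tie-breaking: among equal-score structures prefer fewer
    pairs, then the pair with the smaller 5' (and then 3') end at each choice
    point, which yields a reproducible, lexicographically early pair list.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise InputError(f"BPP matrix must be square, got {P.shape}")
    if np.nanmin(P) < -1e-12 or np.nanmax(P) > 1 + 1e-9:
        raise InputError("BPP entries must lie in [0, 1]")
    if gamma <= 0:
        raise InputError("gamma must be positive")
    L = P.shape[0]
    gain = (gamma + 1.0) * P - 1.0   # 0-based [i, j]

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> tuple[float, int]:
        """(score, n_pairs) of the optimal decoding of 0-based [i, j]."""
        if j - i < min_hairpin + 1:
            return (0.0, 0)
        sc, npairs = best(i + 1, j)
        for l in range(i + min_hairpin + 1, j + 1):
            if gain[i, l] <= 0:
                continue
            s1, n1 = best(i + 1, l - 1)
            s2, n2 = best(l + 1, j) if l < j else (0.0, 0)
            cand = (gain[i, l] + s1 + s2, n1 + n2 + 1)
            if cand[0] > sc + 1e-12 or (abs(cand[0] - sc) <= 1e-12
                                        and cand[1] < npairs):
                sc, npairs = cand
        return (sc, npairs)

    pairs: set[tuple[int, int]] = set()

    def trace(i: int, j: int) -> None:
        while j - i >= min_hairpin + 1:
            sc, npairs = best(i, j)
            if (sc, npairs) == best(i + 1, j):
                i += 1
                continue
            for l in range(i + min_hairpin + 1, j + 1):
                if gain[i, l] <= 0:
                    continue
                s1, n1 = best(i + 1, l - 1)
                s2, n2 = best(l + 1, j) if l < j else (0.0, 0)
                if (abs(gain[i, l] + s1 + s2 - sc) <= 1e-12
                        and n1 + n2 + 1 == npairs):
                    pairs.add((i + 1, l + 1))  # 1-based
                    trace(i + 1, l - 1)
                    i, j = l + 1, j
                    break
            else:  # numerically unmatched: fall back to unpaired i
                i += 1

    if L > 0:
        trace(0, L - 1)
    best.cache_clear()
    return SecondaryStructure(frozenset(pairs), L, min_hairpin)


def centroid_score(P: np.ndarray, s: SecondaryStructure, gamma: float) -> float:
    """sum over the structure's pairs of ((gamma + 1) P_ij - 1)."""
    return float(sum((gamma + 1.0) * P[i - 1, j - 1] - 1.0 for i, j in s.pairs))


def detect_ranges(dist: DistanceDistribution, Q: float = -10.0,
                  T: float | None = None) -> list[PeakRange]:
    """Split the above-threshold support of p(d) at strict local minima.

    ``Q`` is the threshold free energy in kcal/mol: only distances with
    p(d) > exp(Q / RT) are considered. ``T`` overrides the distribution's own
    temperature for the threshold only.
    """
    RT = dist.RT if T is None else GAS_CONSTANT * T
    theta = float(np.exp(Q / RT))
    p = dist.p
    n = len(p)
    above = p > theta
    if not above.any():
        log.warning("no distance bin exceeds the threshold exp(Q/RT) = %.3e", theta)
        return []

    ranges: list[PeakRange] = []
    k = 0
    while k < n:
        if not above[k]:
            k += 1
            continue
        start = k
        while k + 1 < n and above[k + 1]:
            k += 1
        end = k
        # strict local minima strictly inside the run
        splits = [d for d in range(start + 1, end)
                  if p[d - 1] > p[d] < p[d + 1]]
        bounds = [start] + splits + [end]
        for a, b in zip(bounds[:-1], bounds[1:]):
            mass = float(p[a:b + 1].sum())
            ranges.append(PeakRange(a + dist.d_min, b + dist.d_min, mass))
        k += 1
    shared = sum(1 for r1, r2 in zip(ranges[:-1], ranges[1:])
                 if r1.r_max == r2.r_min)
    if shared:
        log.info("%d boundary bin(s) shared between adjacent ranges; "
                 "per-range masses overlap accordingly", shared)
    return ranges
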