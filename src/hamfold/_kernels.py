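"""Numba kernels: distance-classified inside/outside recursions at one point.

Each kernel evaluates the polynomial dynamic program at a fixed complex point
``x`` on the unit circle (and a second point ``y`` for the two-reference
variant; passing an empty second reference makes every ``y`` exponent zero).
Powers of the evaluation points are table lookups: ``xp[g + off]`` holds
``x**g`` for g in [-off, len(xp) - off).

State conventions (1-based, inclusive intervals; arrays are (L+2) x (L+2)):

* ``Z[i,j]``   — all structures of [i,j];
* ``Z1[i,j]``  — the rightmost outermost pair starts at i, nothing paired
                 after its partner;
* ``Zb[i,j]``  — (i,j) is a pair;
* ``Zm[i,j]``  — inside a multiloop, at least one branch;
* ``Zm1[i,j]`` — inside a multiloop, exactly one branch, starting at i;
* ``Wb[i,j]``  — everything outside the pair (i,j).

The exponent attached to a state counts the symmetric difference between the
predicted pairs of the state's region and the reference pairs lying entirely
within that region (for ``Wb``: reference pairs NOT entirely within [i,j]).
Every transition's gain is therefore the number of reference pairs newly made
unsatisfiable, plus 1 - 2*sigma(i,j) whenever the transition closes pair
(i,j). The outside multiloop scan over enclosing pairs (h,l) is factorized
through intermediates M(i,l) and N(j,h) so one evaluation point costs O(L^3).
"""

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _gz0(cum, i, j):
    if i >= j or i < 0 or j > cum.shape[0] - 1:
        return 0
    return cum[i, j]


@njit(cache=True, inline="always")
def _g0(cum, i, j, h):
    # straddle count for the cut between h and h+1 inside [i, j]; h may be
    # i-1 or j (empty side), giving 0
    return _gz0(cum, i, j) - _gz0(cum, i, h) - _gz0(cum, h + 1, j)


@njit(cache=True)
def inside_kernel(L, pcode, sig1, sig2, cum1, cum2,
                  whp, wstack, wbulge, wintl, wasym, wterm,
                  wml_close, wml_branch, wml_unp,
                  xp1, off1, xp2, off2, spow, minhp, cap):
    Z = np.zeros((L + 2, L + 2), dtype=np.complex128)
    Z1 = np.zeros((L + 2, L + 2), dtype=np.complex128)
    Zb = np.zeros((L + 2, L + 2), dtype=np.complex128)
    Zm = np.zeros((L + 2, L + 2), dtype=np.complex128)
    Zm1 = np.zeros((L + 2, L + 2), dtype=np.complex128)
    wus = wml_unp  # per multiloop-unpaired base (scale folded via spow)

    for span in range(1, L + 1):
        for i in range(1, L - span + 2):
            j = i + span - 1

            # ---- Zb: hairpin / two-loop / multiloop closure --------------
            if span >= minhp + 2 and pcode[i, j] >= 0:
                s1 = sig1[i, j]
                s2 = sig2[i, j]
                g1 = _gz0(cum1, i, j) + 1 - 2 * s1
                g2 = _gz0(cum2, i, j) + 1 - 2 * s2
                acc = whp[i, j] * spow[span] * xp1[g1 + off1] * xp2[g2 + off2]
                hmax = min(j - minhp - 2, i + cap + 1)
                pc_ij = pcode[i, j]
                for h in range(i + 1, hmax + 1):
                    n1 = h - i - 1
                    lmin = max(h + minhp + 1, j - 1 - (cap - n1))
                    for l in range(lmin, j):
                        if pcode[h, l] < 0:
                            continue
                        zb = Zb[h, l]
                        if zb == 0:
                            continue
                        n2 = j - l - 1
                        if n1 == 0 and n2 == 0:
                            w = wstack[pc_ij, pcode[h, l]]
                        elif n1 == 0 or n2 == 0:
                            w = wbulge[n1 + n2] * wterm[pc_ij] * wterm[pcode[h, l]]
                        else:
                            w = (wintl[n1 + n2] * wasym[abs(n1 - n2)]
                                 * wterm[pc_ij] * wterm[pcode[h, l]])
                        e1 = _gz0(cum1, i, j) - _gz0(cum1, h, l) + 1 - 2 * s1
                        e2 = _gz0(cum2, i, j) - _gz0(cum2, h, l) + 1 - 2 * s2
                        acc += (w * spow[span - (l - h + 1)] * zb
                                * xp1[e1 + off1] * xp2[e2 + off2])
                for h in range(i + minhp + 3, j - minhp - 1):
                    zm = Zm[i + 1, h - 1]
                    zm1 = Zm1[h, j - 1]
                    if zm == 0 or zm1 == 0:
                        continue
                    e1 = (_gz0(cum1, i, j) - _gz0(cum1, i + 1, h - 1)
                          - _gz0(cum1, h, j - 1) + 1 - 2 * s1)
                    e2 = (_gz0(cum2, i, j) - _gz0(cum2, i + 1, h - 1)
                          - _gz0(cum2, h, j - 1) + 1 - 2 * s2)
                    acc += (wml_close * spow[2] * zm * zm1
                            * xp1[e1 + off1] * xp2[e2 + off2])
                Zb[i, j] = acc

            # ---- Z1 / Zm1: one pair starting at i, tail unpaired ---------
            acc1 = 0.0 + 0.0j
            accm1 = 0.0 + 0.0j
            tail_ml = 1.0
            for l in range(j, i + minhp, -1):
                zb = Zb[i, l]
                if zb != 0:
                    e1 = _g0(cum1, i, j, l) + _gz0(cum1, l + 1, j)
                    e2 = _g0(cum2, i, j, l) + _gz0(cum2, l + 1, j)
                    pw = xp1[e1 + off1] * xp2[e2 + off2]
                    acc1 += zb * spow[j - l] * pw
                    accm1 += zb * wml_branch * tail_ml * spow[j - l] * pw
                tail_ml *= wus
            Z1[i, j] = acc1
            Zm1[i, j] = accm1

            # ---- Zm: >= 1 branch in a multiloop --------------------------
            accm = 0.0 + 0.0j
            lead_ml = 1.0
            for h in range(i, j - minhp):
                zm1 = Zm1[h, j]
                if zm1 != 0:
                    e1 = _g0(cum1, i, j, h - 1)
                    e2 = _g0(cum2, i, j, h - 1)
                    first = (lead_ml * spow[h - i]
                             * xp1[_gz0(cum1, i, h - 1) + off1]
                             * xp2[_gz0(cum2, i, h - 1) + off2])
                    left = first + (Zm[i, h - 1] if h > i else 0.0)
                    accm += left * zm1 * xp1[e1 + off1] * xp2[e2 + off2]
                lead_ml *= wus
            Zm[i, j] = accm

            # ---- Z: empty + bifurcation over the last outer pair ---------
            acc = (spow[span] * xp1[_gz0(cum1, i, j) + off1]
                   * xp2[_gz0(cum2, i, j) + off2])
            for h in range(i, j - minhp):
                z1 = Z1[h, j]
                if z1 != 0:
                    left = Z[i, h - 1] if h > i else 1.0 + 0.0j
                    e1 = _g0(cum1, i, j, h - 1)
                    e2 = _g0(cum2, i, j, h - 1)
                    acc += left * z1 * xp1[e1 + off1] * xp2[e2 + off2]
            Z[i, j] = acc

    return Z, Z1, Zb, Zm, Zm1


@njit(cache=True)
def outside_kernel(L, pcode, sig1, sig2, cum1, cum2,
                   wstack, wbulge, wintl, wasym, wterm,
                   wml_close, wml_branch, wml_unp,
                   xp1, off1, xp2, off2, spow, minhp, cap,
                   Z, Zm, Zb):
    Wb = np.zeros((L + 2, L + 2), dtype=np.complex128)
    M = np.zeros((L + 2, L + 2), dtype=np.complex128)
    N = np.zeros((L + 2, L + 2), dtype=np.complex128)
    mdone = np.zeros((L + 2, L + 2), dtype=np.uint8)
    ndone = np.zeros((L + 2, L + 2), dtype=np.uint8)
    wus = wml_unp
    gz1L_1 = _gz0(cum1, 1, L)
    gz1L_2 = _gz0(cum2, 1, L)

    for span in range(L, minhp + 1, -1):
        for i in range(1, L - span + 2):
            j = i + span - 1
            if pcode[i, j] < 0:
                continue
            gzij_1 = _gz0(cum1, i, j)
            gzij_2 = _gz0(cum2, i, j)

            # (11) exterior: no enclosing pair
            zl = Z[1, i - 1] if i > 1 else 1.0 + 0.0j
            zr = Z[j + 1, L] if j < L else 1.0 + 0.0j
            e1 = gz1L_1 - gzij_1 - _gz0(cum1, 1, i - 1) - _gz0(cum1, j + 1, L)
            e2 = gz1L_2 - gzij_2 - _gz0(cum2, 1, i - 1) - _gz0(cum2, j + 1, L)
            acc = zl * zr * xp1[e1 + off1] * xp2[e2 + off2]

            # (12) enclosed by (h,l) through a two-loop
            pc_ij = pcode[i, j]
            for h in range(max(1, i - cap - 1), i):
                n1 = i - h - 1
                lmax = min(L, j + 1 + (cap - n1))
                for l in range(j + 1, lmax + 1):
                    if pcode[h, l] < 0:
                        continue
                    wb = Wb[h, l]
                    if wb == 0:
                        continue
                    n2 = l - j - 1
                    if n1 == 0 and n2 == 0:
                        w = wstack[pcode[h, l], pc_ij]
                    elif n1 == 0 or n2 == 0:
                        w = wbulge[n1 + n2] * wterm[pcode[h, l]] * wterm[pc_ij]
                    else:
                        w = (wintl[n1 + n2] * wasym[abs(n1 - n2)]
                             * wterm[pcode[h, l]] * wterm[pc_ij])
                    e1 = _gz0(cum1, h, l) - gzij_1 + 1 - 2 * sig1[h, l]
                    e2 = _gz0(cum2, h, l) - gzij_2 + 1 - 2 * sig2[h, l]
                    acc += (wb * w * spow[(l - h) - (j - i)]
                            * xp1[e1 + off1] * xp2[e2 + off2])

            # (13) enclosed by (h,l) closing a multiloop.
            # M[i,l] = sum_h Wb[h,l] Zm[h+1,i-1] * x^{gz0(h,l)+1-2sig(h,l)-gz0(h+1,i-1)}
            # N[j,h] = sum_l Wb[h,l] Zm[j+1,l-1] * x^{gz0(h,l)+1-2sig(h,l)-gz0(j+1,l-1)}
            for l in range(j + 1, L + 1):
                if not mdone[i, l]:
                    m = 0.0 + 0.0j
                    for h in range(1, i - 1):
                        if pcode[h, l] < 0:
                            continue
                        wb = Wb[h, l]
                        zm = Zm[h + 1, i - 1]
                        if wb == 0 or zm == 0:
                            continue
                        e1 = (_gz0(cum1, h, l) + 1 - 2 * sig1[h, l]
                              - _gz0(cum1, h + 1, i - 1))
                        e2 = (_gz0(cum2, h, l) + 1 - 2 * sig2[h, l]
                              - _gz0(cum2, h + 1, i - 1))
                        m += wb * zm * xp1[e1 + off1] * xp2[e2 + off2]
                    # wml_close covers the enclosing pair's own a + b terms;
                    # the (i,j) branch contributes one more b
                    M[i, l] = m * wml_close * wml_branch * spow[2]
                    mdone[i, l] = 1
            # branches only 5' of i: 3' flank (j,l) unpaired
            tail = 1.0
            for l in range(j + 1, L + 1):
                ml = M[i, l]
                if ml != 0:
                    acc += (ml * tail * spow[l - 1 - j]
                            * xp1[-gzij_1 + off1] * xp2[-gzij_2 + off2])
                tail *= wus
            # branches on both flanks
            for l in range(j + 2, L + 1):
                ml = M[i, l]
                zm = Zm[j + 1, l - 1]
                if ml == 0 or zm == 0:
                    continue
                e1 = -gzij_1 - _gz0(cum1, j + 1, l - 1)
                e2 = -gzij_2 - _gz0(cum2, j + 1, l - 1)
                acc += ml * zm * xp1[e1 + off1] * xp2[e2 + off2]
            # branches only 3' of j: 5' flank (h,i) unpaired
            for h in range(1, i):
                if not ndone[j, h]:
                    n = 0.0 + 0.0j
                    for l in range(j + 2, L + 1):
                        if pcode[h, l] < 0:
                            continue
                        wb = Wb[h, l]
                        zm = Zm[j + 1, l - 1]
                        if wb == 0 or zm == 0:
                            continue
                        e1 = (_gz0(cum1, h, l) + 1 - 2 * sig1[h, l]
                              - _gz0(cum1, j + 1, l - 1))
                        e2 = (_gz0(cum2, h, l) + 1 - 2 * sig2[h, l]
                              - _gz0(cum2, j + 1, l - 1))
                        n += wb * zm * xp1[e1 + off1] * xp2[e2 + off2]
                    N[j, h] = n * wml_close * wml_branch * spow[2]
                    ndone[j, h] = 1
            lead = 1.0
            for h in range(i - 1, 0, -1):
                nv = N[j, h]
                if nv != 0:
                    acc += (nv * lead * spow[i - 1 - h]
                            * xp1[-gzij_1 + off1] * xp2[-gzij_2 + off2])
                lead *= wus

            Wb[i, j] = acc

    return Wb
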