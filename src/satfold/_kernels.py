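"""Numba dynamic-programming kernels for the folding engine.

Grammar (unambiguous, shared by the MFE minimization and the partition
function so that every structure is generated exactly once):

  F   exterior prefix; branches and quadruplexes separated by unpaired bases
  V   substructure closed by pair (i,j); decompositions: hairpin,
      stack on (i+1,j-1), interior/bulge to an inner *branch*, multiloop
  BR  a branch: under no-lonely-pairs this is stack(i,j)+V(i+1,j-1)
      (outer pair forced to stack inward), otherwise plain V(i,j)
  M   multiloop segment with >= 1 branch, first-branch decomposition
  M1  multiloop segment whose last branch starts at its left end,
      followed only by unpaired bases

Under no-lonely-pairs every helix therefore has >= 2 stacked pairs,
exactly matching a post-filter on enumerated structures.  Energies are
kcal/mol; INF marks impossible states.  Partition-function tables are
scaled by kappa per nucleotide to keep 10 kb folds finite.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

INF = np.inf
MAXLOOP = 30


@njit(cache=True)
def _loop_e(size, tab, lxc):
    if size <= MAXLOOP:
        return tab[size]
    return tab[MAXLOOP] + lxc * math.log(size / MAXLOOP)


@njit(cache=True)
def _hairpin_e(s, i, j, pt, hp, mism, atp, lxc):
    size = j - i - 1
    e = _loop_e(size, hp, lxc)
    if size == 3:
        e += atp[pt]
    else:
        e += mism[pt, s[i + 1], s[j - 1]]
    return e


@njit(cache=True)
def _two_pair_e(s, i, j, k, l, ptij, ptlk, stack, bu, it, mism, atp,
                ninio_m, ninio_x, lxc):
    """Loop closed by (i,j) with inner pair (k,l); not the adjacent-stack case."""
    n1 = k - i - 1
    n2 = j - l - 1
    if n1 == 0 or n2 == 0:
        size = n1 + n2
        e = _loop_e(size, bu, lxc)
        if size == 1:
            e += stack[ptij, ptlk]
        else:
            e += atp[ptij] + atp[ptlk]
        return e
    e = _loop_e(n1 + n2, it, lxc)
    nin = ninio_m * abs(n1 - n2)
    if nin > ninio_x:
        nin = ninio_x
    e += nin
    e += mism[ptij, s[i + 1], s[j - 1]]
    e += mism[ptlk, s[l + 1], s[k - 1]]
    return e


@njit(cache=True)
def fill_gquad(s, a_coeff, b_coeff):
    """Minimum quadruplex energy and layer count per [i, j] span.

    A quadruplex is four G-runs of equal length L (2..5) separated by
    three linkers of 1..7 nt; energy a*(L-1) + b*ln(ltot-2).  Also
    returns the layout count per (i, j, best configuration) basis:
    ``gcount[i, j]`` sums Boltzmann-relevant layout multiplicities and
    is consumed by the partition function as sum_layouts exp(-E/RT)
    computed there (here we only record feasibility and min energy per
    (L) with counts per ltot handled in gweight).
    """
    n = s.shape[0]
    gmfe = np.full((n, n), INF)
    glayers = np.zeros((n, n), dtype=np.int8)
    grun = np.zeros(n + 1, dtype=np.int32)
    for i in range(n - 1, -1, -1):
        if s[i] == 3:
            grun[i] = grun[i + 1] + 1
    for i in range(n):
        for L in range(2, 6):
            if grun[i] < L:
                continue
            for ltot in range(3, 22):
                span = 4 * L + ltot
                j = i + span - 1
                if j >= n:
                    break
                if grun[j - L + 1] < L:
                    continue
                ok = False
                for l1 in range(1, 8):
                    if ok:
                        break
                    for l2 in range(1, 8):
                        l3 = ltot - l1 - l2
                        if l3 < 1 or l3 > 7:
                            continue
                        r2 = i + L + l1
                        r3 = r2 + L + l2
                        if grun[r2] >= L and grun[r3] >= L:
                            ok = True
                            break
                if ok:
                    e = a_coeff * (L - 1) + b_coeff * math.log(ltot - 2.0)
                    if e < gmfe[i, j]:
                        gmfe[i, j] = e
                        glayers[i, j] = L
    return gmfe, glayers


@njit(cache=True)
def fill_gquad_weights(s, a_coeff, b_coeff, rt):
    """Sum of Boltzmann weights over all quadruplex layouts per [i, j]."""
    n = s.shape[0]
    gw = np.zeros((n, n))
    grun = np.zeros(n + 1, dtype=np.int32)
    for i in range(n - 1, -1, -1):
        if s[i] == 3:
            grun[i] = grun[i + 1] + 1
    for i in range(n):
        for L in range(2, 6):
            if grun[i] < L:
                continue
            for ltot in range(3, 22):
                span = 4 * L + ltot
                j = i + span - 1
                if j >= n:
                    break
                if grun[j - L + 1] < L:
                    continue
                count = 0
                for l1 in range(1, 8):
                    for l2 in range(1, 8):
                        l3 = ltot - l1 - l2
                        if l3 < 1 or l3 > 7:
                            continue
                        r2 = i + L + l1
                        r3 = r2 + L + l2
                        if grun[r2] >= L and grun[r3] >= L:
                            count += 1
                if count > 0:
                    e = a_coeff * (L - 1) + b_coeff * math.log(ltot - 2.0)
                    gw[i, j] += count * math.exp(-e / rt)
    return gw


@njit(cache=True)
def _branch_v(V, s, i, j, pairidx, stack, nolp):
    """Energy of segment [i,j] as a branch closed by (i,j) (INF if impossible)."""
    ptij = pairidx[s[i], s[j]]
    if ptij == 0 or j - i < 4:
        return INF
    if not nolp:
        return V[i, j]
    if j - i < 6:
        return INF
    pin = pairidx[s[i + 1], s[j - 1]]
    if pin == 0:
        return INF
    rin = pairidx[s[j - 1], s[i + 1]]
    return stack[ptij, rin] + V[i + 1, j - 1]


@njit(cache=True)
def fill_mfe(s, pairidx, stack, mism, d5, d3, hp, bu, it, atp,
             ml_u, ml_c, ml_b, ninio_m, ninio_x, lxc, gmfe, nolp):
    n = s.shape[0]
    V = np.full((n, n), INF)
    M = np.full((n, n), INF)
    M1 = np.full((n, n), INF)
    F = np.zeros(n + 1)
    minspan = 6 if nolp else 4
    for d in range(4, n):
        for i in range(0, n - d):
            j = i + d
            ptij = pairidx[s[i], s[j]]
            if ptij > 0:
                best = _hairpin_e(s, i, j, ptij, hp, mism, atp, lxc)
                # adjacent stack (always via V of the inner pair)
                if d >= 6:
                    pin = pairidx[s[i + 1], s[j - 1]]
                    if pin > 0:
                        rin = pairidx[s[j - 1], s[i + 1]]
                        cand = stack[ptij, rin] + V[i + 1, j - 1]
                        if cand < best:
                            best = cand
                # interior / bulge to an inner branch
                kmax = min(i + MAXLOOP + 1, j - minspan - 1)
                for k in range(i + 1, kmax + 1):
                    n1 = k - i - 1
                    lmin = j - 1 - (MAXLOOP - n1)
                    if lmin < k + minspan:
                        lmin = k + minspan
                    for l in range(lmin, j):
                        if k == i + 1 and l == j - 1:
                            continue
                        br = _branch_v(V, s, k, l, pairidx, stack, nolp)
                        if br < INF:
                            ptlk = pairidx[s[l], s[k]]
                            e = _two_pair_e(s, i, j, k, l, ptij, ptlk, stack,
                                            bu, it, mism, atp, ninio_m, ninio_x, lxc)
                            cand = e + br
                            if cand < best:
                                best = cand
                # multiloop
                ptji = pairidx[s[j], s[i]]
                base = ml_c + ml_b + atp[ptij] + d5[ptji, s[j - 1]] + d3[ptji, s[i + 1]]
                for h in range(i + 2, j - 4):
                    if M[i + 1, h - 1] < INF and M1[h, j - 1] < INF:
                        cand = base + M[i + 1, h - 1] + M1[h, j - 1]
                        if cand < best:
                            best = cand
                V[i, j] = best
            # multiloop segment tables (only contexts with both neighbors inside)
            if i >= 1 and j <= n - 2:
                best1 = INF
                bestm = M[i + 1, j] + ml_u
                for l in range(i + minspan, j + 1):
                    br = _branch_v(V, s, i, l, pairidx, stack, nolp)
                    if br < INF:
                        pt = pairidx[s[i], s[l]]
                        eb = br + ml_b + atp[pt] + d5[pt, s[i - 1]] + d3[pt, s[l + 1]]
                    else:
                        eb = INF
                    g = gmfe[i, l]
                    if g < INF:
                        g = g + ml_b
                    for which in range(2):
                        v = eb if which == 0 else g
                        if v >= INF:
                            continue
                        cand = v + ml_u * (j - l)
                        if cand < best1:
                            best1 = cand
                        if cand < bestm:
                            bestm = cand
                        if l + 1 <= j and M[l + 1, j] < INF:
                            cand2 = v + M[l + 1, j]
                            if cand2 < bestm:
                                bestm = cand2
                M1[i, j] = best1
                M[i, j] = bestm
    # exterior
    for k in range(1, n + 1):
        j = k - 1
        best = F[k - 1]
        for i in range(0, j - 3):
            br = _branch_v(V, s, i, j, pairidx, stack, nolp)
            if br < INF:
                pt = pairidx[s[i], s[j]]
                e = br + atp[pt]
                if i > 0:
                    e += d5[pt, s[i - 1]]
                if j < n - 1:
                    e += d3[pt, s[j + 1]]
                cand = F[i] + e
                if cand < best:
                    best = cand
            if gmfe[i, j] < INF:
                cand = F[i] + gmfe[i, j]
                if cand < best:
                    best = cand
        F[k] = best
    return V, M, M1, F


@njit(cache=True)
def _qbranch(QV, s, i, j, pairidx, stack, kappa2, rt, nolp):
    """Boltzmann weight of segment [i,j] as a branch (0 if impossible)."""
    ptij = pairidx[s[i], s[j]]
    if ptij == 0 or j - i < 4:
        return 0.0
    if not nolp:
        return QV[i, j]
    if j - i < 6:
        return 0.0
    pin = pairidx[s[i + 1], s[j - 1]]
    if pin == 0:
        return 0.0
    rin = pairidx[s[j - 1], s[i + 1]]
    return math.exp(-stack[ptij, rin] / rt) * kappa2 * QV[i + 1, j - 1]


@njit(cache=True)
def fill_pf(s, pairidx, stack, mism, d5, d3, hp, bu, it, atp,
            ml_u, ml_c, ml_b, ninio_m, ninio_x, lxc, gw, nolp, kappa, rt):
    n = s.shape[0]
    QV = np.zeros((n, n))
    QM = np.zeros((n, n))
    QM1 = np.zeros((n, n))
    QF = np.zeros(n + 1)
    QFr = np.zeros(n + 1)
    kpow = np.ones(n + 2)
    for t in range(1, n + 2):
        kpow[t] = kpow[t - 1] * kappa
    wu = kappa * math.exp(-ml_u / rt)
    wupow = np.ones(n + 1)
    for t in range(1, n + 1):
        wupow[t] = wupow[t - 1] * wu
    wb = math.exp(-ml_b / rt)
    kappa2 = kappa * kappa
    minspan = 6 if nolp else 4
    for d in range(4, n):
        for i in range(0, n - d):
            j = i + d
            ptij = pairidx[s[i], s[j]]
            if ptij > 0:
                q = math.exp(-_hairpin_e(s, i, j, ptij, hp, mism, atp, lxc) / rt) \
                    * kpow[d + 1]
                if d >= 6:
                    pin = pairidx[s[i + 1], s[j - 1]]
                    if pin > 0:
                        rin = pairidx[s[j - 1], s[i + 1]]
                        q += math.exp(-stack[ptij, rin] / rt) * kappa2 * QV[i + 1, j - 1]
                kmax = min(i + MAXLOOP + 1, j - minspan - 1)
                for k in range(i + 1, kmax + 1):
                    n1 = k - i - 1
                    lmin = j - 1 - (MAXLOOP - n1)
                    if lmin < k + minspan:
                        lmin = k + minspan
                    for l in range(lmin, j):
                        if k == i + 1 and l == j - 1:
                            continue
                        qb = _qbranch(QV, s, k, l, pairidx, stack, kappa2, rt, nolp)
                        if qb > 0.0:
                            ptlk = pairidx[s[l], s[k]]
                            e = _two_pair_e(s, i, j, k, l, ptij, ptlk, stack,
                                            bu, it, mism, atp, ninio_m, ninio_x, lxc)
                            n2 = j - l - 1
                            q += math.exp(-e / rt) * kpow[n1 + n2 + 2] * qb
                ptji = pairidx[s[j], s[i]]
                base = ml_c + ml_b + atp[ptij] + d5[ptji, s[j - 1]] + d3[ptji, s[i + 1]]
                wclose = math.exp(-base / rt) * kappa2
                acc = 0.0
                for h in range(i + 2, j - 4):
                    acc += QM[i + 1, h - 1] * QM1[h, j - 1]
                q += wclose * acc
                QV[i, j] = q
            if i >= 1 and j <= n - 2:
                q1 = 0.0
                qm = wu * QM[i + 1, j]
                for l in range(i + minspan, j + 1):
                    qb = _qbranch(QV, s, i, l, pairidx, stack, kappa2, rt, nolp)
                    tot = 0.0
                    if qb > 0.0:
                        pt = pairidx[s[i], s[l]]
                        ebr = atp[pt] + d5[pt, s[i - 1]] + d3[pt, s[l + 1]]
                        tot = qb * wb * math.exp(-ebr / rt)
                    if gw[i, l] > 0.0:
                        tot += gw[i, l] * kpow[l - i + 1] * wb
                    if tot > 0.0:
                        q1 += tot * wupow[j - l]
                        qm += tot * (wupow[j - l] + QM[l + 1, j])
                QM1[i, j] = q1
                QM[i, j] = qm
    QF[0] = 1.0
    for k in range(1, n + 1):
        j = k - 1
        q = QF[k - 1] * kappa
        for i in range(0, j - 3):
            qb = _qbranch(QV, s, i, j, pairidx, stack, kappa2, rt, nolp)
            if qb > 0.0:
                pt = pairidx[s[i], s[j]]
                e = atp[pt]
                if i > 0:
                    e += d5[pt, s[i - 1]]
                if j < n - 1:
                    e += d3[pt, s[j + 1]]
                q += QF[i] * qb * math.exp(-e / rt)
            if gw[i, j] > 0.0:
                q += QF[i] * gw[i, j] * kpow[j - i + 1]
        QF[k] = q
    QFr[n] = 1.0
    for i in range(n - 1, -1, -1):
        q = QFr[i + 1] * kappa
        for j in range(i + 4, n):
            qb = _qbranch(QV, s, i, j, pairidx, stack, kappa2, rt, nolp)
            if qb > 0.0:
                pt = pairidx[s[i], s[j]]
                e = atp[pt]
                if i > 0:
                    e += d5[pt, s[i - 1]]
                if j < n - 1:
                    e += d3[pt, s[j + 1]]
                q += qb * math.exp(-e / rt) * QFr[j + 1]
            if gw[i, j] > 0.0:
                q += gw[i, j] * kpow[j - i + 1] * QFr[j + 1]
        QFr[i] = q
    return QV, QM, QM1, QF, QFr


@njit(cache=True)
def fill_outside(s, pairidx, stack, mism, d5, d3, hp, bu, it, atp,
                 ml_u, ml_c, ml_b, ninio_m, ninio_x, lxc, gw, nolp, kappa, rt,
                 QV, QM, QM1, QF, QFr):
    """Outside (exterior) weights and the base-pair probability matrix."""
    n = s.shape[0]
    OV = np.zeros((n, n))
    OVS = np.zeros((n, n))
    OM = np.zeros((n, n))
    OM1 = np.zeros((n, n))
    kpow = np.ones(n + 2)
    for t in range(1, n + 2):
        kpow[t] = kpow[t - 1] * kappa
    wu = kappa * math.exp(-ml_u / rt)
    wupow = np.ones(n + 1)
    for t in range(1, n + 1):
        wupow[t] = wupow[t - 1] * wu
    wb = math.exp(-ml_b / rt)
    kappa2 = kappa * kappa
    minspan = 6 if nolp else 4
    Z = QF[n]
    # exterior contexts for every branch
    for i in range(0, n - 4):
        for j in range(i + 4, n):
            ptij = pairidx[s[i], s[j]]
            if ptij == 0:
                continue
            e = atp[ptij]
            if i > 0:
                e += d5[ptij, s[i - 1]]
            if j < n - 1:
                e += d3[ptij, s[j + 1]]
            OVS[i, j] += QF[i] * math.exp(-e / rt) * QFr[j + 1]
    for d in range(n - 1, 3, -1):
        for i in range(0, n - d):
            j = i + d
            # --- consume OM[i,j]
            if OM[i, j] > 0.0 and i >= 1 and j <= n - 2:
                om = OM[i, j]
                OM[i + 1, j] += om * wu
                for l in range(i + minspan, j + 1):
                    qb = _qbranch(QV, s, i, l, pairidx, stack, kappa2, rt, nolp)
                    gq = gw[i, l] * kpow[l - i + 1] * wb if gw[i, l] > 0.0 else 0.0
                    wbr = 0.0
                    if qb > 0.0:
                        pt = pairidx[s[i], s[l]]
                        ebr = atp[pt] + d5[pt, s[i - 1]] + d3[pt, s[l + 1]]
                        wbr = wb * math.exp(-ebr / rt)
                    rest = wupow[j - l] + (QM[l + 1, j] if l + 1 <= j else 0.0)
                    if wbr > 0.0:
                        OVS[i, l] += om * rest * wbr
                    tot = qb * wbr + gq
                    if tot > 0.0 and l + 1 <= j:
                        OM[l + 1, j] += om * tot
            # --- consume OM1[i,j]
            if OM1[i, j] > 0.0 and i >= 1 and j <= n - 2:
                om1 = OM1[i, j]
                for l in range(i + minspan, j + 1):
                    qb = _qbranch(QV, s, i, l, pairidx, stack, kappa2, rt, nolp)
                    if qb > 0.0:
                        pt = pairidx[s[i], s[l]]
                        ebr = atp[pt] + d5[pt, s[i - 1]] + d3[pt, s[l + 1]]
                        OVS[i, l] += om1 * wupow[j - l] * wb * math.exp(-ebr / rt)
            # --- branch weight transfer
            if not nolp:
                OV[i, j] += OVS[i, j]
            ptij = pairidx[s[i], s[j]]
            if ptij == 0:
                continue
            if nolp and OVS[i, j] > 0.0 and d >= 6:
                pin = pairidx[s[i + 1], s[j - 1]]
                if pin > 0:
                    rin = pairidx[s[j - 1], s[i + 1]]
                    OV[i + 1, j - 1] += OVS[i, j] * math.exp(-stack[ptij, rin] / rt) * kappa2
            # --- consume OV[i,j] over the decompositions of QV[i,j]
            ov = OV[i, j]
            if ov <= 0.0:
                continue
            if d >= 6:
                pin = pairidx[s[i + 1], s[j - 1]]
                if pin > 0:
                    rin = pairidx[s[j - 1], s[i + 1]]
                    OV[i + 1, j - 1] += ov * math.exp(-stack[ptij, rin] / rt) * kappa2
            kmax = min(i + MAXLOOP + 1, j - minspan - 1)
            for k in range(i + 1, kmax + 1):
                n1 = k - i - 1
                lmin = j - 1 - (MAXLOOP - n1)
                if lmin < k + minspan:
                    lmin = k + minspan
                for l in range(lmin, j):
                    if k == i + 1 and l == j - 1:
                        continue
                    qb = _qbranch(QV, s, k, l, pairidx, stack, kappa2, rt, nolp)
                    if qb > 0.0:
                        ptlk = pairidx[s[l], s[k]]
                        e = _two_pair_e(s, i, j, k, l, ptij, ptlk, stack,
                                        bu, it, mism, atp, ninio_m, ninio_x, lxc)
                        n2 = j - l - 1
                        OVS[k, l] += ov * math.exp(-e / rt) * kpow[n1 + n2 + 2]
            ptji = pairidx[s[j], s[i]]
            base = ml_c + ml_b + atp[ptij] + d5[ptji, s[j - 1]] + d3[ptji, s[i + 1]]
            wclose = math.exp(-base / rt) * kappa2
            for h in range(i + 2, j - 4):
                OM[i + 1, h - 1] += ov * wclose * QM1[h, j - 1]
                OM1[h, j - 1] += ov * wclose * QM[i + 1, h - 1]
    # pair probabilities
    P = np.zeros((n, n))
    for i in range(0, n - 4):
        for j in range(i + 4, n):
            w = OV[i, j] * QV[i, j]
            if nolp:
                w += OVS[i, j] * _qbranch(QV, s, i, j, pairidx, stack, kappa2, rt, nolp)
            if w > 0.0:
                p = w / Z
                P[i, j] = p
                P[j, i] = p
    return P
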