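"""Loop-decomposition free energy of an explicit secondary structure.

The total free energy of a structure is the sum of the contributing
terms of its loops: stabilizing stacked base pairs and destabilizing
hairpin, bulge, interior and multibranch loops, plus end contributions
(both-side dangles in the d2 convention, terminal mismatches, and the
terminal A.T penalty).  ``structure_energy`` evaluates this sum for any
explicit structure; the dynamic-programming fold in :mod:`satfold.fold`
minimizes / sums exactly the same terms, which is what the
brute-force-vs-DP oracle tests exploit.

Model conventions (applied identically everywhere):

* stack (i,j)/(i+1,j-1): ``stack[pt(i,j), pt(j-1,i+1)]``
* hairpin of size s: length penalty; size 3 adds the terminal A.T
  penalty, size > 3 adds the terminal mismatch of the closing pair
* bulge of size 1 keeps the flanking stack term; larger bulges add the
  terminal A.T penalty at both closing pairs
* interior loop: length penalty + asymmetry (ninio, capped) + terminal
  mismatches at both closing pairs
* multiloop: linear model a + b*(branches + 1) + c*unpaired, closing
  pair and every branch add d2 dangles on both sides plus the terminal
  A.T penalty
* exterior branches: d2 dangles where a neighbor base exists, plus the
  terminal A.T penalty
* G-quadruplex runs score a*(L-1) + b*ln(ltot-2) and count as branches
  when enclosed in a loop
"""

from __future__ import annotations

import numpy as np

from .params import EnergyParameters
from .sequence import encode
from .structure import SecondaryStructure, StructureError

__all__ = ["structure_energy", "loop_decomposition"]


def _atp(params: EnergyParameters, pt: int) -> float:
    # AT, TA and (when enabled) GT, TG helix ends pay the terminal penalty
    return params.terminal_at if pt in (3, 4, 5, 6) else 0.0


def _pt(params: EnergyParameters, s: np.ndarray, i: int, j: int) -> int:
    pt = params.pair_type(int(s[i]), int(s[j]))
    if pt == 0:
        raise StructureError(
            f"disallowed pair ({i},{j}): "
            f"{'NACGT'[s[i]]}-{'NACGT'[s[j]]} cannot pair under these parameters"
        )
    return pt


def two_pair_loop_energy(
    params: EnergyParameters, s: np.ndarray, i: int, j: int, k: int, l: int
) -> float:
    """Energy of the loop closed by (i,j) with single inner pair (k,l)."""
    ptij = _pt(params, s, i, j)
    ptlk = _pt(params, s, l, k)  # inner pair seen from the loop
    n1, n2 = k - i - 1, j - l - 1
    if n1 == 0 and n2 == 0:
        return float(params.stack[ptij, ptlk])
    if n1 == 0 or n2 == 0:
        size = n1 + n2
        e = params.bulge_energy_by_size(size)
        if size == 1:
            e += float(params.stack[ptij, ptlk])
        else:
            e += _atp(params, ptij) + _atp(params, ptlk)
        return e
    e = params.interior_energy_by_size(n1 + n2)
    e += min(params.ninio_max, params.ninio_slope * abs(n1 - n2))
    e += float(params.terminal_mismatch[ptij, s[i + 1], s[j - 1]])
    e += float(params.terminal_mismatch[ptlk, s[l + 1], s[k - 1]])
    return e


def hairpin_energy(params: EnergyParameters, s: np.ndarray, i: int, j: int) -> float:
    ptij = _pt(params, s, i, j)
    size = j - i - 1
    e = params.hairpin_energy_by_size(size)
    if size == 3:
        e += _atp(params, ptij)
    else:
        e += float(params.terminal_mismatch[ptij, s[i + 1], s[j - 1]])
    return e


def multiloop_energy(
    params: EnergyParameters,
    s: np.ndarray,
    i: int,
    j: int,
    branches: list[tuple[int, int]],
    gquads: list[tuple[int, int, int]],
    unpaired: int,
) -> float:
    ptij = _pt(params, s, i, j)
    ptji = params.pair_type(int(s[j]), int(s[i]))
    n_elem = len(branches) + len(gquads)
    e = params.ml_closing + params.ml_branch * (n_elem + 1) + params.ml_unpaired * unpaired
    e += _atp(params, ptij)
    # closing pair seen from inside the loop: 5' neighbor is j-1, 3' is i+1
    e += float(params.dangle5[ptji, s[j - 1]]) + float(params.dangle3[ptji, s[i + 1]])
    for k, l in branches:
        ptkl = _pt(params, s, k, l)
        e += _atp(params, ptkl)
        e += float(params.dangle5[ptkl, s[k - 1]]) + float(params.dangle3[ptkl, s[l + 1]])
    for a, b, layers in gquads:
        e += params.gquad_energy(layers, (b - a) - 4 * layers)
    return e


def exterior_branch_energy(
    params: EnergyParameters, s: np.ndarray, i: int, j: int
) -> float:
    """d2 end terms of a top-level helix (i,j); the helix itself is scored inside."""
    ptij = _pt(params, s, i, j)
    e = _atp(params, ptij)
    if i > 0:
        e += float(params.dangle5[ptij, s[i - 1]])
    if j < len(s) - 1:
        e += float(params.dangle3[ptij, s[j + 1]])
    return e


def loop_decomposition(structure: SecondaryStructure):
    """Yield (closing pair or None, direct child pairs, direct child gquads,
    unpaired count) for every loop, exterior first."""
    pairs = list(structure.pairs)
    gquads = list(structure.gquads)

    def children(lo: int, hi: int):
        """Direct children strictly inside (lo, hi)."""
        kids: list[tuple[int, int]] = []
        gkids: list[tuple[int, int, int]] = []
        covered = 0
        pos = lo + 1
        unpaired = 0
        events = sorted(
            [(i, j, "p") for i, j in pairs if lo < i and j < hi]
            + [(a, b - 1, "g") for a, b, ly in gquads if lo < a and b - 1 < hi],
        )
        while pos < hi:
            nxt = None
            for a, b, kind in events:
                if a >= pos:
                    nxt = (a, b, kind)
                    break
            if nxt is None:
                unpaired += hi - pos
                break
            a, b, kind = nxt
            unpaired += a - pos
            if kind == "p":
                kids.append((a, b))
            else:
                for g in gquads:
                    if g[0] == a:
                        gkids.append(g)
                        break
            pos = b + 1
        return kids, gkids, unpaired

    out = []
    kids, gkids, unp = children(-1, structure.length)
    out.append((None, kids, gkids, unp))
    stack = list(kids)
    while stack:
        i, j = stack.pop()
        kids, gkids, unp = children(i, j)
        out.append(((i, j), kids, gkids, unp))
        stack.extend(kids)
    return out


def structure_energy(
    seq: str | np.ndarray,
    structure: SecondaryStructure,
    params: EnergyParameters,
) -> float:
    """Free energy (kcal/mol) of ``structure`` on ``seq`` under ``params``.

    The open chain scores exactly 0.  Raises :class:`StructureError` for
    invalid structures or disallowed pairs (N never pairs).
    """
    s = encode(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.int8)
    if structure.length != len(s):
        raise StructureError(
            f"structure length {structure.length} != sequence length {len(s)}"
        )
    total = 0.0
    for closing, kids, gkids, unp in loop_decomposition(structure):
        if closing is None:
            for k, l in kids:
                total += exterior_branch_energy(params, s, k, l)
            for a, b, layers in gkids:
                total += params.gquad_energy(layers, (b - a) - 4 * layers)
        else:
            i, j = closing
            if not kids and not gkids:
                total += hairpin_energy(params, s, i, j)
            elif len(kids) == 1 and not gkids:
                k, l = kids[0]
                total += two_pair_loop_energy(params, s, i, j, k, l)
            else:
                total += multiloop_energy(params, s, i, j, kids, gkids, unp)
    return total
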