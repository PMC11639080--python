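"""Exhaustive enumeration of secondary structures for short sequences.

Brute-force generation of every pseudoknot-free structure (hairpin
loops >= 3 unpaired bases, pairs restricted to those the parameter set
allows, N never pairs), optionally restricted to canonical
no-lonely-pair structures.  This is the independent oracle the folding
engine is validated against: the DP minimum must equal the minimum of
:func:`satfold.energy.structure_energy` over this list, and the
partition function must equal the explicit Boltzmann sum.  Guarded to
20 nt; counts explode beyond that.

G-quadruplexes are deliberately outside this enumeration; oracle
comparisons run with ``gquad=False``.
"""

from __future__ import annotations

import numpy as np

from .fold import FoldOptions
from .params import EnergyParameters, RT_KCAL
from .sequence import encode
from .structure import SecondaryStructure

__all__ = ["enumerate_structures", "boltzmann_ensemble"]

MAX_ENUM_LENGTH = 20


def enumerate_structures(
    seq: str,
    params: EnergyParameters,
    opts: FoldOptions = FoldOptions(),
) -> list[SecondaryStructure]:
    """All valid structures of ``seq`` (the open chain included).

    With ``opts.no_lonely_pairs`` only canonical structures (every pair
    stacked on a neighbor) are returned, matching the DP restriction.
    """
    s = encode(seq)
    n = len(s)
    if n > MAX_ENUM_LENGTH:
        raise ValueError(f"enumeration guarded to {MAX_ENUM_LENGTH} nt, got {n}")

    def pairable(i: int, j: int) -> bool:
        return params.pair_type(int(s[i]), int(s[j])) > 0

    cache: dict[tuple[int, int], list[tuple[tuple[int, int], ...]]] = {}

    def segment(i: int, j: int) -> list[tuple[tuple[int, int], ...]]:
        """Structures on s[i..j] inclusive."""
        if j - i + 1 < 5:
            return [()]
        key = (i, j)
        if key in cache:
            return cache[key]
        out: list[tuple[tuple[int, int], ...]] = []
        # i unpaired
        out.extend(segment(i + 1, j))
        # i paired with k
        for k in range(i + 4, j + 1):
            if not pairable(i, k):
                continue
            for inner in segment(i + 1, k - 1):
                closed = ((i, k),) + inner
                for rest in segment(k + 1, j):
                    out.append(closed + rest)
        cache[key] = out
        return out

    structures = [
        SecondaryStructure(length=n, pairs=p) for p in segment(0, n - 1)
    ]
    if opts.no_lonely_pairs:
        structures = [st for st in structures if st.is_canonical()]
    return structures


def boltzmann_ensemble(
    seq: str,
    params: EnergyParameters,
    opts: FoldOptions = FoldOptions(),
):
    """Explicit Boltzmann ensemble for a short sequence.

    Returns (structures, energies, weights, Z, pair probability matrix,
    mean pairwise base-pair distance) computed by direct summation --
    the reference values for partition-function tests.
    """
    from .energy import structure_energy

    structures = enumerate_structures(seq, params, opts)
    energies = np.array([structure_energy(seq, st, params) for st in structures])
    weights = np.exp(-energies / RT_KCAL)
    Z = float(weights.sum())
    n = len(seq)
    P = np.zeros((n, n))
    for st, w in zip(structures, weights):
        for i, j in st.pairs:
            P[i, j] += w
    P /= Z
    P = P + P.T
    # expected distance between two independent draws
    probs = weights / Z
    dist = 0.0
    for a, st_a in enumerate(structures):
        pa = set(st_a.pairs)
        for b, st_b in enumerate(structures):
            dist += probs[a] * probs[b] * len(pa ^ set(st_b.pairs))
    return structures, energies, weights, Z, P, dist
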