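"""MFE folding, partition function and ensemble statistics for ssDNA.

``fold_mfe`` runs the Zuker-style minimization over the loop-based
model, ``partition_function`` the McCaskill-style sum (ensemble free
energy ``-RT ln Z``, base-pair probability matrix) and
``ensemble_diversity`` the expected base-pair distance between two
independent draws from the Boltzmann ensemble.  Defaults mirror the
reference folding command for DNA: d2 dangles (both-side end
contributions added unconditionally at every helix end), no lonely
pairs, G-quadruplexes enabled, no U-to-T conversion.

The traceback re-derives the decisions of the DP matrices with the same
floating-point operation order as the kernels, so the recovered
structure's :func:`satfold.energy.structure_energy` equals the reported
MFE exactly (a property the test-suite asserts against brute-force
enumeration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .energy import structure_energy
from .params import EnergyParameters, RT_KCAL, PAIR_INDEX
from .sequence import encode
from .structure import SecondaryStructure

__all__ = [
    "FoldOptions",
    "FoldResult",
    "fold_mfe",
    "partition_function",
    "fold",
    "ensemble_diversity",
    "round_energy",
]

_TOL = 1e-9
_PF_SCALE_FACTOR = 1.05


@dataclass(frozen=True)
class FoldOptions:
    """Folding options; the defaults reproduce the study's command line."""

    dangle_model: str = "d2"
    no_lonely_pairs: bool = True
    gquad: bool = True

    def __post_init__(self) -> None:
        if self.dangle_model != "d2":
            raise ValueError("only the d2 dangle model is implemented")


@dataclass
class FoldResult:
    """Folding outputs for one sequence (energies in kcal/mol)."""

    structure: SecondaryStructure | None = None
    mfe: float = 0.0
    ensemble_free_energy: float | None = None
    bp_prob: np.ndarray | None = None
    ensemble_diversity: float | None = None
    seq_id: str = ""

    @property
    def mfe_report(self) -> float:
        return round_energy(self.mfe)

    def dotbracket(self) -> str:
        return self.structure.to_dotbracket() if self.structure is not None else ""


def round_energy(x: float) -> float:
    """Round to 2 decimals, half away from zero (report convention)."""
    return math.copysign(math.floor(abs(x) * 100.0 + 0.5) / 100.0, x)


def _tables(params: EnergyParameters):
    allowed = params.allowed_pairs
    pairidx = PAIR_INDEX.copy()
    for pt in range(1, 7):
        if not allowed[pt]:
            pairidx[pairidx == pt] = 0
    atp = np.zeros(8)
    for pt in (3, 4, 5, 6):
        atp[pt] = params.terminal_at
    return (
        pairidx,
        params.stack,
        params.terminal_mismatch,
        params.dangle5,
        params.dangle3,
        params.hairpin,
        params.bulge,
        params.interior,
        atp,
        params.ml_unpaired,
        params.ml_closing,
        params.ml_branch,
        params.ninio_slope,
        params.ninio_max,
        params.lxc,
    )


def _gquad_tables(s: np.ndarray, params: EnergyParameters, opts: FoldOptions):
    n = len(s)
    if opts.gquad:
        gmfe, glayers = K.fill_gquad(
            s, params.gquad_stack_coeff, params.gquad_linker_coeff
        )
    else:
        gmfe = np.full((n, n), np.inf)
        glayers = np.zeros((n, n), dtype=np.int8)
    return gmfe, glayers


class _Trace:
    """Python-side traceback over the filled MFE matrices.

    Candidate energies are recomputed with the exact operation order of
    the numba kernels; ties are broken by preferring a pairing
    decomposition and scanning candidates in ascending start position.
    """

    def __init__(self, s, tabs, gmfe, glayers, nolp, V, M, M1, F):
        (self.pairidx, self.stack, self.mism, self.d5, self.d3, self.hp,
         self.bu, self.it, self.atp, self.ml_u, self.ml_c, self.ml_b,
         self.ninio_m, self.ninio_x, self.lxc) = tabs
        self.s = s
        self.n = len(s)
        self.gmfe = gmfe
        self.glayers = glayers
        self.nolp = nolp
        self.minspan = 6 if nolp else 4
        self.V, self.M, self.M1, self.F = V, M, M1, F
        self.pairs: list[tuple[int, int]] = []
        self.gquads: list[tuple[int, int, int]] = []

    # -- energy terms, mirroring _kernels op order --------------------
    def pt(self, i, j):
        return int(self.pairidx[self.s[i], self.s[j]])

    def loop_e(self, size, tab):
        if size <= K.MAXLOOP:
            return float(tab[size])
        return float(tab[K.MAXLOOP]) + self.lxc * math.log(size / K.MAXLOOP)

    def hairpin_e(self, i, j, pt):
        size = j - i - 1
        e = self.loop_e(size, self.hp)
        if size == 3:
            e += self.atp[pt]
        else:
            e += float(self.mism[pt, self.s[i + 1], self.s[j - 1]])
        return e

    def two_pair_e(self, i, j, k, l, ptij, ptlk):
        n1, n2 = k - i - 1, j - l - 1
        if n1 == 0 or n2 == 0:
            size = n1 + n2
            e = self.loop_e(size, self.bu)
            if size == 1:
                e += float(self.stack[ptij, ptlk])
            else:
                e += self.atp[ptij] + self.atp[ptlk]
            return e
        e = self.loop_e(n1 + n2, self.it)
        nin = self.ninio_m * abs(n1 - n2)
        if nin > self.ninio_x:
            nin = self.ninio_x
        e += nin
        e += float(self.mism[ptij, self.s[i + 1], self.s[j - 1]])
        e += float(self.mism[ptlk, self.s[l + 1], self.s[k - 1]])
        return e

    def branch_v(self, i, j):
        ptij = self.pt(i, j)
        if ptij == 0 or j - i < 4:
            return np.inf
        if not self.nolp:
            return float(self.V[i, j])
        if j - i < 6:
            return np.inf
        if self.pt(i + 1, j - 1) == 0:
            return np.inf
        rin = self.pt(j - 1, i + 1)
        return float(self.stack[ptij, rin]) + float(self.V[i + 1, j - 1])

    def ml_branch_e(self, i, l):
        br = self.branch_v(i, l)
        if not np.isfinite(br):
            return np.inf
        pt = self.pt(i, l)
        return (br + self.ml_b + self.atp[pt]
                + float(self.d5[pt, self.s[i - 1]]) + float(self.d3[pt, self.s[l + 1]]))

    def ext_branch_e(self, i, j):
        br = self.branch_v(i, j)
        if not np.isfinite(br):
            return np.inf
        pt = self.pt(i, j)
        e = br + self.atp[pt]
        if i > 0:
            e += float(self.d5[pt, self.s[i - 1]])
        if j < self.n - 1:
            e += float(self.d3[pt, self.s[j + 1]])
        return e

    # -- traceback ----------------------------------------------------
    def emit_branch(self, i, j):
        """Record the outer pair(s) of a branch and descend into V."""
        self.pairs.append((i, j))
        if self.nolp:
            self.pairs.append((i + 1, j - 1))
            self.trace_v(i + 1, j - 1)
        else:
            self.trace_v(i, j)

    def emit_gquad(self, i, j):
        self.gquads.append((i, j + 1, int(self.glayers[i, j])))

    def trace_f(self):
        k = self.n
        while k > 4:
            j = k - 1
            target = float(self.F[k])
            if abs(target - float(self.F[k - 1])) < _TOL and target == 0.0:
                k -= 1
                continue
            hit = False
            for i in range(0, j - 3):
                e = self.ext_branch_e(i, j)
                if np.isfinite(e) and abs(float(self.F[i]) + e - target) < _TOL:
                    self.emit_branch(i, j)
                    k = i
                    hit = True
                    break
                g = float(self.gmfe[i, j])
                if np.isfinite(g) and abs(float(self.F[i]) + g - target) < _TOL:
                    self.emit_gquad(i, j)
                    k = i
                    hit = True
                    break
            if not hit:
                if abs(target - float(self.F[k - 1])) < _TOL:
                    k -= 1
                else:  # pragma: no cover - defensive
                    raise RuntimeError(f"exterior traceback failed at {k}")
        return self

    def trace_v(self, i, j):
        target = float(self.V[i, j])
        ptij = self.pt(i, j)
        # stack
        if j - i >= 6 and self.pt(i + 1, j - 1) > 0:
            rin = self.pt(j - 1, i + 1)
            cand = float(self.stack[ptij, rin]) + float(self.V[i + 1, j - 1])
            if abs(cand - target) < _TOL:
                self.pairs.append((i + 1, j - 1))
                self.trace_v(i + 1, j - 1)
                return
        # interior / bulge
        kmax = min(i + K.MAXLOOP + 1, j - self.minspan - 1)
        for k in range(i + 1, kmax + 1):
            n1 = k - i - 1
            lmin = max(j - 1 - (K.MAXLOOP - n1), k + self.minspan)
            for l in range(lmin, j):
                if k == i + 1 and l == j - 1:
                    continue
                br = self.branch_v(k, l)
                if not np.isfinite(br):
                    continue
                ptlk = self.pt(l, k)
                e = self.two_pair_e(i, j, k, l, ptij, ptlk)
                if abs(e + br - target) < _TOL:
                    self.emit_branch(k, l)
                    return
        # multiloop
        ptji = self.pt(j, i)
        base = (self.ml_c + self.ml_b + self.atp[ptij]
                + float(self.d5[ptji, self.s[j - 1]])
                + float(self.d3[ptji, self.s[i + 1]]))
        for h in range(i + 2, j - 4):
            m, m1 = float(self.M[i + 1, h - 1]), float(self.M1[h, j - 1])
            if np.isfinite(m) and np.isfinite(m1) and abs(base + m + m1 - target) < _TOL:
                self.trace_m(i + 1, h - 1)
                self.trace_m1(h, j - 1)
                return
        # hairpin
        if abs(self.hairpin_e(i, j, ptij) - target) < _TOL:
            return
        raise RuntimeError(f"V traceback failed at ({i},{j})")  # pragma: no cover

    def trace_m(self, i, j):
        target = float(self.M[i, j])
        for l in range(i + self.minspan, j + 1):
            eb = self.ml_branch_e(i, l)
            gq = float(self.gmfe[i, l])
            gqe = gq + self.ml_b if np.isfinite(gq) else np.inf
            for v, is_g in ((eb, False), (gqe, True)):
                if not np.isfinite(v):
                    continue
                if l + 1 <= j and np.isfinite(self.M[l + 1, j]) \
                        and abs(v + float(self.M[l + 1, j]) - target) < _TOL:
                    (self.emit_gquad if is_g else self.emit_branch)(i, l)
                    self.trace_m(l + 1, j)
                    return
                if abs(v + self.ml_u * (j - l) - target) < _TOL:
                    (self.emit_gquad if is_g else self.emit_branch)(i, l)
                    return
        if abs(float(self.M[i + 1, j]) + self.ml_u - target) < _TOL:
            self.trace_m(i + 1, j)
            return
        raise RuntimeError(f"M traceback failed at ({i},{j})")  # pragma: no cover

    def trace_m1(self, i, j):
        target = float(self.M1[i, j])
        for l in range(i + self.minspan, j + 1):
            eb = self.ml_branch_e(i, l)
            if np.isfinite(eb) and abs(eb + self.ml_u * (j - l) - target) < _TOL:
                self.emit_branch(i, l)
                return
            gq = float(self.gmfe[i, l])
            if np.isfinite(gq) and abs(gq + self.ml_b + self.ml_u * (j - l) - target) < _TOL:
                self.emit_gquad(i, l)
                return
        raise RuntimeError(f"M1 traceback failed at ({i},{j})")  # pragma: no cover


def _prepare(seq, params):
    s = encode(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.int8)
    if len(s) == 0:
        raise ValueError("empty sequence")
    return s


def fold_mfe(
    seq: str | np.ndarray,
    params: EnergyParameters,
    opts: FoldOptions = FoldOptions(),
) -> FoldResult:
    """Minimum-free-energy structure of a single-stranded DNA sequence.

    Returns the open chain with MFE 0.0 when no structure is
    stabilizing.  N never pairs.
    """
    s = _prepare(seq, params)
    n = len(s)
    tabs = _tables(params)
    gmfe, glayers = _gquad_tables(s, params, opts)
    if n < 5:
        return FoldResult(structure=SecondaryStructure(length=n), mfe=0.0)
    V, M, M1, F = K.fill_mfe(s, *tabs, gmfe, opts.no_lonely_pairs)
    mfe = float(F[n])
    if mfe >= 0.0:
        return FoldResult(structure=SecondaryStructure(length=n), mfe=0.0)
    tr = _Trace(s, tabs, gmfe, glayers, opts.no_lonely_pairs, V, M, M1, F).trace_f()
    structure = SecondaryStructure(length=n, pairs=tuple(tr.pairs),
                                   gquads=tuple(tr.gquads))
    return FoldResult(structure=structure, mfe=mfe)


def partition_function(
    seq: str | np.ndarray,
    params: EnergyParameters,
    opts: FoldOptions = FoldOptions(),
    compute_bppm: bool = True,
) -> FoldResult:
    """Ensemble free energy -RT ln Z and base-pair probabilities.

    The DP is rescaled per nucleotide using the MFE so that weights stay
    finite for sequences up to ~10 kb.
    """
    s = _prepare(seq, params)
    n = len(s)
    res = fold_mfe(s, params, opts)
    if n < 5:
        res.ensemble_free_energy = 0.0
        res.bp_prob = np.zeros((n, n))
        res.ensemble_diversity = 0.0
        return res
    tabs = _tables(params)
    if opts.gquad:
        gw = K.fill_gquad_weights(s, params.gquad_stack_coeff,
                                  params.gquad_linker_coeff, RT_KCAL)
    else:
        gw = np.zeros((n, n))
    kappa = math.exp(_PF_SCALE_FACTOR * res.mfe / (n * RT_KCAL)) if res.mfe < 0 else 1.0
    QV, QM, QM1, QF, QFr = K.fill_pf(s, *tabs, gw, opts.no_lonely_pairs, kappa, RT_KCAL)
    if not (QF[n] > 0.0 and math.isfinite(QF[n])):  # pragma: no cover - guard
        raise FloatingPointError("partition function over/underflow")
    res.ensemble_free_energy = -RT_KCAL * (math.log(QF[n]) - n * math.log(kappa))
    if compute_bppm:
        P = K.fill_outside(s, *tabs, gw, opts.no_lonely_pairs, kappa, RT_KCAL,
                           QV, QM, QM1, QF, QFr)
        res.bp_prob = P
        res.ensemble_diversity = ensemble_diversity(P)
    return res


def fold(
    seq: str | np.ndarray,
    params: EnergyParameters,
    opts: FoldOptions = FoldOptions(),
) -> FoldResult:
    """MFE + ensemble quantities in one call."""
    return partition_function(seq, params, opts, compute_bppm=True)


def ensemble_diversity(bp_prob: np.ndarray) -> float:
    """Expected base-pair distance between two ensemble draws.

    <d> = 2 * sum_{i<j} p_ij (1 - p_ij): a pair contributes when present
    in one draw and absent in the other.
    """
    P = np.asarray(bp_prob, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("bp_prob must be a square matrix")
    if ((P < -1e-9) | (P > 1 + 1e-9)).any():
        raise ValueError("pair probabilities outside [0, 1]")
    iu = np.triu_indices(P.shape[0], k=1)
    p = np.clip(P[iu], 0.0, 1.0)
    return float(2.0 * np.sum(p * (1.0 - p)))


def verify_traceback(result: FoldResult, seq: str, params: EnergyParameters) -> float:
    """Recompute the traceback structure's energy (pairs only; no gquads)."""
    if result.structure is None or result.structure.gquads:
        raise ValueError("verification requires a pair-only structure")
    return structure_energy(seq, result.structure, params)
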