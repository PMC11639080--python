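"""Dyad symmetries and the seven non-B DNA motif classes.

Detects inverted repeats (cruciform-forming dyad symmetries), mirror
repeats (triplex), direct repeats (slipped structures), A-phased
repeats (bent DNA), alternating purine-pyrimidine tracts (Z-DNA), G4
motifs (G-quadruplexes) and short tandem repeats, plus the
EMBOSS-palindrome-style dyad scan used for dyad density.

Hit semantics (shared with the naive oracles in the test-suite):

* Two-armed motifs (inverted/mirror) live on anti-diagonals of the
  match matrix.  A hit is one maximal run of consecutive arm matches:
  the innermost matching pair within the gap limit, extended outward to
  the last consecutive match, truncated to ``max_arm``.  Sub-arms are
  never emitted separately; ``allow_overlap`` refers to hits with
  distinct centers.
* Direct repeats are maximal match runs at a copy-to-copy shift d =
  unit + spacer; the unit is the longest prefix compatible with the
  run (a run >= d is a tandem repeat with spacer 0).
* Short tandem repeats are maximal intervals with period u in 1..9 and
  total length >= ``str_min_total``; intervals contained in another STR
  interval are dropped (equal intervals keep the smallest unit).
* N matches nothing in any scanner.

Coordinates are 0-based half-open throughout; 1-based conversion only
happens at the report-writing boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .sequence import encode, revcomp

__all__ = [
    "MotifHit",
    "PalindromeParams",
    "MotifConfig",
    "find_palindromes",
    "dyad_density",
    "scan_non_b_motifs",
    "motif_occupancy",
    "MOTIF_CLASSES",
]

MOTIF_CLASSES = (
    "inverted_repeat",
    "mirror_repeat",
    "direct_repeat",
    "a_phased",
    "z_dna",
    "g4",
    "str",
)

_COMP = np.array([0, 4, 3, 2, 1], dtype=np.int8)  # N A C G T -> N T G C A


@dataclass(frozen=True)
class MotifHit:
    """One detected motif; ``start``/``end`` are 0-based half-open."""

    motif_class: str
    start: int
    end: int
    arm_length: int = 0
    spacer_length: int = 0
    unit: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad hit interval [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PalindromeParams:
    """Dyad-scan parameters; defaults reproduce the EMBOSS palindrome
    command used for dyad density (-minpallen 5 -maxpallen 100
    -gaplimit 20 -nummismatches 0 -overlap)."""

    min_arm: int = 5
    max_arm: int = 100
    gap_limit: int = 20
    mismatches: int = 0
    allow_overlap: bool = True

    def __post_init__(self) -> None:
        if self.min_arm < 2:
            raise ValueError("min_arm must be >= 2")
        if self.max_arm < self.min_arm:
            raise ValueError("max_arm must be >= min_arm")
        if self.mismatches != 0:
            raise ValueError("mismatch-tolerant arms are not implemented; use 0")


@dataclass(frozen=True)
class MotifConfig:
    """Per-class thresholds for the seven non-B motif scanners."""

    inverted_min_arm: int = 10
    inverted_max_spacer: int = 100
    mirror_min_arm: int = 10
    mirror_max_spacer: int = 100
    direct_min_unit: int = 10
    direct_max_unit: int = 60
    direct_max_spacer: int = 10
    aphased_min_tracts: int = 3
    aphased_tract_min: int = 3
    aphased_tract_max: int = 9
    aphased_phase: int = 10
    aphased_phase_tol: int = 1
    zdna_min_dinucleotides: int = 10
    g4_min_run: int = 3
    g4_max_linker: int = 7
    str_max_unit: int = 9
    str_min_total: int = 20
    #: suppress mirror/direct hits whose whole region is one repeated base
    #: (homopolymer runs are reported as short tandem repeats instead)
    exclude_homopolymer_arms: bool = True


@njit(cache=True)
def _dyad_scan_kernel(s, other, min_arm, max_arm, gap_limit):
    """Maximal-run arm matches per anti-diagonal.

    Only runs whose innermost pair lies within the gap limit qualify,
    so each anti-diagonal needs O(gap_limit/2) probes plus the arm
    extension; output rows are (start, end_exclusive, arm, gap).
    """
    n = s.shape[0]
    cap = n * (gap_limit // 2 + 2) + 64
    buf = np.empty((cap, 4), dtype=np.int64)
    cnt = 0
    for sig in range(1, 2 * n - 2):
        x_hi = (sig - 1) // 2
        x_lo = sig - n + 1
        if x_lo < 0:
            x_lo = 0
        if x_hi < x_lo:
            continue
        b_min = (sig - gap_limit) // 2
        if b_min < x_lo:
            b_min = x_lo
        x = x_hi
        while x >= b_min:
            y = sig - x
            if s[x] != 0 and s[x] == other[y]:
                # innermost point of a run within the gap limit
                arm = 0
                xx = x
                while xx >= x_lo and arm < max_arm and s[xx] != 0 \
                        and s[xx] == other[sig - xx]:
                    arm += 1
                    xx -= 1
                # skip past the remainder of the run if the arm cap hit
                while xx >= x_lo and s[xx] != 0 and s[xx] == other[sig - xx]:
                    xx -= 1
                if arm >= min_arm:
                    start = x - arm + 1
                    buf[cnt, 0] = start
                    buf[cnt, 1] = sig - start + 1
                    buf[cnt, 2] = arm
                    buf[cnt, 3] = sig - 2 * x - 1
                    cnt += 1
                x = xx
            else:
                x -= 1
    return buf[:cnt]


def _diagonal_hits(s: np.ndarray, motif_class: str, min_arm: int, max_arm: int,
                   gap_limit: int, mirror: bool) -> list[MotifHit]:
    """Maximal-run hits on anti-diagonals (inverted or mirror symmetry)."""
    other = s if mirror else _COMP[s]
    rows = _dyad_scan_kernel(s, other, min_arm, max_arm, gap_limit)
    hits = [
        MotifHit(motif_class, int(a), int(b), arm_length=int(arm),
                 spacer_length=int(gap))
        for a, b, arm, gap in rows
    ]
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def _drop_overlaps(hits: list[MotifHit]) -> list[MotifHit]:
    """Greedy longest-first non-overlapping selection."""
    kept: list[MotifHit] = []
    for h in sorted(hits, key=lambda h: (-h.length, h.start)):
        if all(h.end <= k.start or h.start >= k.end for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: (h.start, h.end))
    return kept


def find_palindromes(seq: str, p: PalindromeParams = PalindromeParams()) -> list[MotifHit]:
    """All maximal dyad symmetries (inverted repeats) of ``seq``.

    Each hit records both arm intervals via start/end + arm/spacer
    geometry: arms are [start, start+arm) and [end-arm, end).
    """
    s = encode(seq)
    hits = _diagonal_hits(s, "palindrome", p.min_arm, p.max_arm, p.gap_limit,
                          mirror=False)
    if not p.allow_overlap:
        hits = _drop_overlaps(hits)
    return hits


def dyad_density(seq_length: int, hits: list[MotifHit]) -> float:
    """Summed palindromic-arm length over sequence length.

    The palindromic region counts both arms (2 x arm) and excludes the
    unpaired spacer; the sum is literal (no overlap deduplication), so
    pathological inputs can exceed 1 and are reported as-is.
    """
    if seq_length <= 0:
        raise ValueError("seq_length must be positive")
    total = sum(2 * h.arm_length for h in hits)
    density = total / seq_length
    if density > 1.0:
        import warnings

        warnings.warn(f"dyad density {density:.3f} exceeds 1 (overlapping hits)")
    return density


# ---------------------------------------------------------------- non-B scanners


def _is_homopolymer(s: np.ndarray, start: int, end: int) -> bool:
    seg = s[start:end]
    return bool(len(seg) > 0 and (seg == seg[0]).all())


def _direct_repeats(s: np.ndarray, cfg: MotifConfig) -> list[MotifHit]:
    n = len(s)
    hits = []
    seq = s
    for d in range(cfg.direct_min_unit, min(cfg.direct_max_unit + cfg.direct_max_spacer, n - 1) + 1):
        m = (seq[: n - d] == seq[d:]) & (seq[: n - d] != 0)
        padded = np.concatenate(([False], m, [False]))
        diff = np.diff(padded.astype(np.int8))
        for a, b in zip(np.nonzero(diff == 1)[0], np.nonzero(diff == -1)[0]):
            run = b - a  # match run length at offset d starting at a
            unit = min(run, d, cfg.direct_max_unit)
            spacer = d - unit
            if unit >= cfg.direct_min_unit and spacer <= cfg.direct_max_spacer:
                if cfg.exclude_homopolymer_arms and _is_homopolymer(s, a, a + d + unit):
                    continue
                hits.append(MotifHit("direct_repeat", a, a + d + unit,
                                     arm_length=unit, spacer_length=spacer,
                                     unit="".join("NACGT"[c] for c in s[a:a + unit])))
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def _short_tandem_repeats(s: np.ndarray, cfg: MotifConfig) -> list[MotifHit]:
    n = len(s)
    intervals: dict[tuple[int, int], int] = {}
    for u in range(1, cfg.str_max_unit + 1):
        if n <= u:
            break
        m = (s[: n - u] == s[u:]) & (s[: n - u] != 0)
        padded = np.concatenate(([False], m, [False]))
        diff = np.diff(padded.astype(np.int8))
        for a, b in zip(np.nonzero(diff == 1)[0], np.nonzero(diff == -1)[0]):
            total = (b - a) + u  # interval [a, a + run + u)
            if total >= cfg.str_min_total and (b - a) >= u:
                key = (a, a + total)
                if key not in intervals or intervals[key] > u:
                    intervals[key] = u
    # drop intervals strictly contained in another
    kept = []
    items = sorted(intervals.items())
    for (a, b), u in items:
        contained = any(
            (a2 <= a and b <= b2) and (a2, b2) != (a, b) for (a2, b2) in intervals
        )
        if not contained:
            kept.append(MotifHit("str", a, b, arm_length=0, spacer_length=0,
                                 unit="".join("NACGT"[c] for c in s[a:a + u])))
    kept.sort(key=lambda h: (h.start, h.end))
    return kept


def _z_dna(s: np.ndarray, cfg: MotifConfig) -> list[MotifHit]:
    n = len(s)
    purine = (s == 1) | (s == 3)
    valid = s != 0
    hits = []
    i = 0
    while i < n - 1:
        if not valid[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and valid[j + 1] and purine[j + 1] != purine[j]:
            j += 1
        run = j - i + 1
        if run >= 2 * cfg.zdna_min_dinucleotides:
            hits.append(MotifHit("z_dna", i, i + (run - run % 2)))
        i = j + 1
    return hits


def _g4(s: np.ndarray, cfg: MotifConfig) -> list[MotifHit]:
    """Chains of >= 4 G-runs (>= g4_min_run) with linkers 1..g4_max_linker."""
    n = len(s)
    runs = []  # (start, end) of maximal G runs of sufficient length
    i = 0
    while i < n:
        if s[i] == 3:
            j = i
            while j + 1 < n and s[j + 1] == 3:
                j += 1
            if j - i + 1 >= cfg.g4_min_run:
                runs.append((i, j + 1))
            i = j + 1
        else:
            i += 1
    hits = []
    k = 0
    while k < len(runs):
        chain_end = k
        while (chain_end + 1 < len(runs)
               and 1 <= runs[chain_end + 1][0] - runs[chain_end][1] <= cfg.g4_max_linker):
            chain_end += 1
        if chain_end - k + 1 >= 4:
            hits.append(MotifHit("g4", runs[k][0], runs[chain_end][1]))
        k = chain_end + 1
    return hits


def _a_phased(s: np.ndarray, cfg: MotifConfig) -> list[MotifHit]:
    """>= aphased_min_tracts A-tracts (or T-tracts) of 3-9 nt at ~10 nt phasing."""
    hits = []
    for base in (1, 4):  # A tracts and T tracts separately
        tracts = []
        n = len(s)
        i = 0
        while i < n:
            if s[i] == base:
                j = i
                while j + 1 < n and s[j + 1] == base:
                    j += 1
                if cfg.aphased_tract_min <= j - i + 1 <= cfg.aphased_tract_max:
                    tracts.append((i, j + 1))
                i = j + 1
            else:
                i += 1
        k = 0
        while k < len(tracts):
            chain_end = k
            while chain_end + 1 < len(tracts):
                c1 = (tracts[chain_end][0] + tracts[chain_end][1]) / 2.0
                c2 = (tracts[chain_end + 1][0] + tracts[chain_end + 1][1]) / 2.0
                if abs((c2 - c1) - cfg.aphased_phase) <= cfg.aphased_phase_tol:
                    chain_end += 1
                else:
                    break
            if chain_end - k + 1 >= cfg.aphased_min_tracts:
                hits.append(MotifHit("a_phased", tracts[k][0], tracts[chain_end][1]))
            k = chain_end + 1
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def scan_non_b_motifs(
    seq: str,
    config: MotifConfig = MotifConfig(),
    classes: tuple[str, ...] = MOTIF_CLASSES,
) -> dict[str, list[MotifHit]]:
    """Per-class hit lists for the seven non-B motif families."""
    unknown = set(classes) - set(MOTIF_CLASSES)
    if unknown:
        raise ValueError(f"unknown motif classes: {sorted(unknown)}")
    s = encode(seq)
    out: dict[str, list[MotifHit]] = {}
    for cls in classes:
        if cls == "inverted_repeat":
            out[cls] = [
                MotifHit(cls, h.start, h.end, h.arm_length, h.spacer_length)
                for h in _diagonal_hits(s, cls, config.inverted_min_arm, 10**9,
                                        config.inverted_max_spacer, mirror=False)
            ]
        elif cls == "mirror_repeat":
            mh = _diagonal_hits(s, cls, config.mirror_min_arm, 10**9,
                                config.mirror_max_spacer, mirror=True)
            if config.exclude_homopolymer_arms:
                mh = [h for h in mh if not _is_homopolymer(s, h.start, h.end)]
            out[cls] = mh
        elif cls == "direct_repeat":
            out[cls] = _direct_repeats(s, config)
        elif cls == "a_phased":
            out[cls] = _a_phased(s, config)
        elif cls == "z_dna":
            out[cls] = _z_dna(s, config)
        elif cls == "g4":
            out[cls] = _g4(s, config)
        elif cls == "str":
            out[cls] = _short_tandem_repeats(s, config)
    return out


def motif_occupancy(
    hits_by_class: dict[str, list[MotifHit]], total_length: int
) -> dict[str, float]:
    """Per class: summed hit length over total region length (literal sum)."""
    if total_length <= 0:
        raise ValueError("total_length must be positive")
    return {
        cls: sum(h.length for h in hits) / total_length
        for cls, hits in hits_by_class.items()
    }


def hits_to_bed(hits: list[MotifHit], chrom: str) -> str:
    """BED6 text for a hit list (name = class, score = arm length)."""
    lines = [
        f"{chrom}\t{h.start}\t{h.end}\t{h.motif_class}\t{h.arm_length}\t+"
        for h in hits
    ]
    return "\n".join(lines) + ("\n" if lines else "")
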