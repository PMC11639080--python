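"""Naive reference scanners used as independent oracles.

Deliberately simple character-level implementations of the motif
definitions (anti-diagonal maximal runs, shift runs, regex-style
linear scans) -- no numpy vectorization, no numba, no shared code with
satfold.motifs beyond the written definitions.
"""

from __future__ import annotations

import re

COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "?"}


def naive_two_arm(seq: str, min_arm: int, max_arm: int, gap_limit: int,
                  mirror: bool) -> list[tuple[int, int, int, int]]:
    """(start, end, arm, gap) hits: one per maximal anti-diagonal run
    whose innermost pair lies within the gap limit."""
    n = len(seq)

    def match(x: int, y: int) -> bool:
        if seq[x] == "N" or seq[y] == "N":
            return False
        return seq[x] == seq[y] if mirror else seq[x] == COMP[seq[y]]

    out = []
    for sig in range(1, 2 * n - 2):
        x_hi = (sig - 1) // 2
        x_lo = max(0, sig - n + 1)
        if x_hi < x_lo:
            continue
        x = x_hi
        while x >= x_lo:
            if match(x, sig - x):
                # find the whole run [a..b], b innermost
                b = x
                a = x
                while a - 1 >= x_lo and match(a - 1, sig - (a - 1)):
                    a -= 1
                gap = sig - 2 * b - 1
                if gap <= gap_limit:
                    arm = min(b - a + 1, max_arm)
                    if arm >= min_arm:
                        start = b - arm + 1
                        out.append((start, sig - start + 1, arm, gap))
                x = a - 1
            else:
                x -= 1
    return sorted(out)


def naive_direct(seq: str, min_unit: int, max_unit: int, max_spacer: int,
                 exclude_homopolymer: bool = True) -> list[tuple[int, int, int, int]]:
    """(start, end, unit_len, spacer) per maximal run at each copy shift."""
    n = len(seq)
    out = []
    for d in range(min_unit, min(max_unit + max_spacer, n - 1) + 1):
        x = 0
        while x < n - d:
            if seq[x] != "N" and seq[x] == seq[x + d]:
                a = x
                while x < n - d and seq[x] != "N" and seq[x] == seq[x + d]:
                    x += 1
                run = x - a
                unit = min(run, d, max_unit)
                spacer = d - unit
                if unit >= min_unit and spacer <= max_spacer:
                    region = seq[a:a + d + unit]
                    if not (exclude_homopolymer and len(set(region)) == 1):
                        out.append((a, a + d + unit, unit, spacer))
            else:
                x += 1
    return sorted(out)


def naive_str(seq: str, max_unit: int, min_total: int) -> list[tuple[int, int, str]]:
    n = len(seq)
    intervals: dict[tuple[int, int], int] = {}
    for u in range(1, max_unit + 1):
        x = 0
        while x < n - u:
            if seq[x] != "N" and seq[x] == seq[x + u]:
                a = x
                while x < n - u and seq[x] != "N" and seq[x] == seq[x + u]:
                    x += 1
                run = x - a
                if run >= u and run + u >= min_total:
                    key = (a, a + run + u)
                    if key not in intervals or intervals[key] > u:
                        intervals[key] = u
            else:
                x += 1
    out = []
    for (a, b), u in sorted(intervals.items()):
        if not any((a2 <= a and b <= b2) and (a2, b2) != (a, b)
                   for (a2, b2) in intervals):
            out.append((a, b, seq[a:a + u]))
    return out


def naive_g4(seq: str, min_run: int = 3, max_linker: int = 7) -> list[tuple[int, int]]:
    runs = [(m.start(), m.end()) for m in re.finditer(f"G{{{min_run},}}", seq)]
    out = []
    k = 0
    while k < len(runs):
        end = k
        while end + 1 < len(runs) and 1 <= runs[end + 1][0] - runs[end][1] <= max_linker:
            end += 1
        if end - k + 1 >= 4:
            out.append((runs[k][0], runs[end][1]))
        k = end + 1
    return out


def naive_zdna(seq: str, min_dinucleotides: int = 10) -> list[tuple[int, int]]:
    ry = seq.translate(str.maketrans("AGCT", "RRYY"))
    out = []
    i = 0
    n = len(seq)
    while i < n - 1:
        if seq[i] == "N":
            i += 1
            continue
        j = i
        while j + 1 < n and seq[j + 1] != "N" and ry[j + 1] != ry[j]:
            j += 1
        run = j - i + 1
        if run >= 2 * min_dinucleotides:
            out.append((i, i + run - run % 2))
        i = j + 1
    return out


def naive_aphased(seq: str, min_tracts: int = 3, tract_min: int = 3,
                  tract_max: int = 9, phase: int = 10, tol: int = 1
                  ) -> list[tuple[int, int]]:
    out = []
    for base in "AT":
        tracts = [
            (m.start(), m.end())
            for m in re.finditer(f"(?<!{base}){base}{{{tract_min},{tract_max}}}(?!{base})",
                                 seq)
        ]
        k = 0
        while k < len(tracts):
            end = k
            while end + 1 < len(tracts):
                c1 = (tracts[end][0] + tracts[end][1]) / 2.0
                c2 = (tracts[end + 1][0] + tracts[end + 1][1]) / 2.0
                if abs((c2 - c1) - phase) <= tol:
                    end += 1
                else:
                    break
            if end - k + 1 >= min_tracts:
                out.append((tracts[k][0], tracts[end][1]))
            k = end + 1
    return sorted(out)
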