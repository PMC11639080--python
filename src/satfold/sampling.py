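"""Region annotations and stochastic sampling of fixed-length windows.

The analysis draws a small number of fixed-length windows (default five
of 4,000 nt; alternates 500 and 1,000) per region class per chromosome.
Chromosomes whose region is absent or smaller than the window length
are excluded -- on the human annotation this reproduces the omission of
chromosome 4 (no divergent higher-order-repeat array) and chromosome X
(divergent array shorter than 4,000 nt).

Windows are drawn uniformly over valid start positions within the
region's intervals, never across interval boundaries, non-overlapping
when feasible; sampling is seed-deterministic.  A table of explicit
window coordinates can bypass the sampler so published coordinates can
be re-profiled directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sequence import NucleotideSequence

__all__ = [
    "GenomicInterval",
    "SamplingPlan",
    "Eligibility",
    "REGION_LABELS",
    "load_region_annotation",
    "check_eligibility",
    "sample_windows",
    "windows_from_table",
]

log = logging.getLogger(__name__)

REGION_LABELS = ("active_hor", "divergent_hor", "centric_transition", "coding", "rdna")


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    region_label: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")
        if self.region_label not in REGION_LABELS:
            raise ValueError(f"unknown region label {self.region_label!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SamplingPlan:
    """How many windows of what length to draw per region per chromosome."""

    n_windows: int = 5
    window_length: int = 4000
    seed: int = 0
    allow_overlap_fallback: bool = True
    max_n_fraction: float = 0.1  # windows with more N than this are redrawn
    max_redraws: int = 50


@dataclass(frozen=True)
class Eligibility:
    eligible: bool
    reason: str = ""


def load_region_annotation(
    bed_path: str | Path, label_map: dict[str, str] | None = None
) -> list[GenomicInterval]:
    """Read a BED3+ annotation; column 4 names resolve through label_map.

    Unknown labels are skipped with a logged warning count; malformed
    lines raise with their line number.
    """
    label_map = label_map or {l: l for l in REGION_LABELS}
    out: list[GenomicInterval] = []
    skipped = 0
    for lineno, line in enumerate(Path(bed_path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"{bed_path}:{lineno}: need >= 4 BED columns")
        chrom, start_s, end_s, name = fields[:4]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ValueError(f"{bed_path}:{lineno}: non-integer coordinates") from exc
        if not (0 <= start < end):
            raise ValueError(f"{bed_path}:{lineno}: bad coordinates {start}-{end}")
        if name not in label_map:
            skipped += 1
            continue
        out.append(GenomicInterval(chrom, start, end, label_map[name]))
    if skipped:
        log.warning("skipped %d intervals with unmapped labels in %s", skipped, bed_path)
    return out


def check_eligibility(
    intervals: list[GenomicInterval], region_label: str, window_length: int
) -> Eligibility:
    """Is this chromosome's region usable at the given window length?"""
    regional = [iv for iv in intervals if iv.region_label == region_label]
    if not regional:
        return Eligibility(False, "region absent")
    span = sum(iv.length for iv in regional)
    if span < window_length:
        return Eligibility(False, "span < window")
    if max(iv.length for iv in regional) < window_length:
        return Eligibility(False, "no interval >= window")
    return Eligibility(True)


def _valid_starts(intervals: list[GenomicInterval], L: int) -> list[tuple[int, int]]:
    """Per interval: (interval index, count of valid starts)."""
    return [(k, iv.length - L + 1) for k, iv in enumerate(intervals) if iv.length >= L]


def sample_windows(
    intervals: list[GenomicInterval],
    genome,
    region_label: str,
    plan: SamplingPlan,
) -> list[NucleotideSequence]:
    """Draw ``plan.n_windows`` windows of exact length from one
    chromosome's region.

    ``genome`` is any mapping of chromosome name to string-like sequence
    (a ``pyfaidx.Fasta`` works).  Starts are uniform over the
    concatenated valid-start space; windows are non-overlapping when
    feasible (with an overlapping fallback that logs a warning);
    N-heavy windows are redrawn up to a bound, then accepted flagged.
    """
    regional = [iv for iv in intervals if iv.region_label == region_label]
    if not regional:
        raise ValueError(f"no {region_label} intervals supplied")
    chrom = regional[0].chrom
    L = plan.window_length
    starts_space = _valid_starts(regional, L)
    total = sum(c for _, c in starts_space)
    if total <= 0:
        raise ValueError(
            f"{chrom}/{region_label}: region too small for a {L} nt window"
        )
    rng = np.random.default_rng(plan.seed)

    def draw() -> tuple[int, int]:
        u = int(rng.integers(total))
        for k, c in starts_space:
            if u < c:
                return k, regional[k].start + u
            u -= c
        raise AssertionError  # pragma: no cover

    chosen: list[tuple[int, int]] = []  # (interval idx, abs start)
    attempts = 0
    overlap_ok = False
    while len(chosen) < plan.n_windows:
        attempts += 1
        if attempts > 200 * plan.n_windows and not overlap_ok:
            if not plan.allow_overlap_fallback:
                raise ValueError(
                    f"{chrom}/{region_label}: cannot place {plan.n_windows} "
                    f"non-overlapping {L} nt windows"
                )
            log.warning("%s/%s: falling back to overlapping windows", chrom, region_label)
            overlap_ok = True
        k, start = draw()
        if any(start == s for _, s in chosen):
            continue
        if not overlap_ok and any(
            k == k2 and abs(start - s2) < L for k2, s2 in chosen
        ):
            continue
        chosen.append((k, start))

    out: list[NucleotideSequence] = []
    for widx, (k, start) in enumerate(sorted(chosen, key=lambda t: t[1])):
        seq = str(genome[chrom][start:start + L]).upper()
        redraws = 0
        while seq.count("N") > plan.max_n_fraction * L and redraws < plan.max_redraws:
            k, start = draw()
            seq = str(genome[chrom][start:start + L]).upper()
            redraws += 1
        ns = NucleotideSequence(
            seq, id=f"{chrom}:{start}-{start + L}:{region_label}:w{widx}",
            chrom=chrom, start=start, region_label=region_label,
        )
        if redraws >= plan.max_redraws:
            log.warning("%s accepted with N content after %d redraws", ns.id, redraws)
        out.append(ns)
    return out


def windows_from_table(
    table_path: str | Path, genome, default_label: str = ""
) -> list[NucleotideSequence]:
    """Load explicit window coordinates (TSV: chrom, start, end[, label]).

    Bypasses stochastic sampling so published coordinates can be
    re-profiled verbatim.
    """
    out = []
    for lineno, line in enumerate(Path(table_path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 3:
            raise ValueError(f"{table_path}:{lineno}: need chrom, start, end")
        chrom, start, end = f[0], int(f[1]), int(f[2])
        label = f[3] if len(f) > 3 else default_label
        seq = str(genome[chrom][start:end]).upper()
        out.append(NucleotideSequence(
            seq, id=f"{chrom}:{start}-{end}:{label}:w{lineno}",
            chrom=chrom, start=start, region_label=label,
        ))
    return out
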