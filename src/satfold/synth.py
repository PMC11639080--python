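"""Synthetic satellite-genome generator with known ground truth.

Emulates the sequence organization the analysis assumes so every
pipeline stage is testable without downloads: alpha-satellite-like
arrays of ~171 nt monomers arranged tandemly into higher-order-repeat
(HOR) units whose copies diverge at a tunable per-base substitution
rate; a GC gradient across region classes (centric transition > active
HOR > divergent HOR, with coding ~0.52 and rDNA-like ~0.65); inserted
dyad symmetries (arm + spacer + reverse complement) at controllable
density; GC-rich rDNA-like sequence carrying mirror repeats (arm +
spacer + reversed, not complemented, arm); and two designed exclusion
chromosomes (one lacking a divergent array, one whose divergent array
is shorter than 4,000 nt).

Everything is seed-deterministic; truth tables (inserted repeat
coordinates, per-region GC targets, unit divergence, a synthetic
per-chromosome missegregation probability table) are returned and
written alongside the FASTA/BED so scanners and samplers can be checked
against construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .sampling import GenomicInterval, REGION_LABELS
from .sequence import revcomp

__all__ = [
    "SyntheticRegionSpec",
    "SyntheticGenome",
    "make_hor_array",
    "insert_dyads",
    "build_fixture_genome",
    "default_gradients_preset",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticRegionSpec:
    """Recipe for one region on one synthetic chromosome."""

    region_label: str
    gc_target: float = 0.4
    seed: int = 0
    # satellite architecture (HOR regions)
    monomer_length: int = 171
    monomers_per_hor: int = 12
    n_hor_units: int = 12
    divergence_rate: float = 0.0
    # non-satellite regions draw i.i.d. sequence of this length
    length: int = 24000
    # inserted two-armed repeats: list of (arm_length, spacer_length, count)
    dyad_insertions: tuple[tuple[int, int, int], ...] = ()
    mirror_insertions: tuple[tuple[int, int, int], ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_target <= 1.0:
            raise ValueError("gc_target must lie in [0, 1]")
        if not 0.0 <= self.divergence_rate < 1.0:
            raise ValueError("divergence_rate must lie in [0, 1)")
        if self.monomer_length < 10:
            raise ValueError("monomer_length must be >= 10")
        if self.region_label not in REGION_LABELS:
            raise ValueError(f"unknown region label {self.region_label!r}")

    @property
    def is_satellite(self) -> bool:
        return self.region_label in ("active_hor", "divergent_hor")

    @property
    def expected_length(self) -> int:
        if self.is_satellite:
            return self.monomer_length * self.monomers_per_hor * self.n_hor_units
        return self.length


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    """Random sequence with *exact* composition at the GC target.

    Fixing counts (rather than sampling i.i.d.) matters for satellite
    regions: one monomer's compositional noise would otherwise be
    amplified across the whole tandem array.
    """
    n_gc = int(round(n * gc))
    n_g = n_gc // 2
    n_a = (n - n_gc) // 2
    arr = np.array(list("G" * n_g + "C" * (n_gc - n_g)
                        + "A" * n_a + "T" * (n - n_gc - n_a)))
    rng.shuffle(arr)
    return "".join(arr)


def make_hor_array(spec: SyntheticRegionSpec) -> str:
    """Tandem HOR array: one random monomer -> HOR unit -> mutated copies.

    A monomer drawn at ``gc_target`` is repeated ``monomers_per_hor``
    times to form the unit; the unit is copied ``n_hor_units`` times,
    each copy independently substituted at ``divergence_rate`` (uniform
    over the three alternative bases, no indels).
    """
    rng = np.random.default_rng(spec.seed)
    monomer = _random_seq(rng, spec.monomer_length, spec.gc_target)
    unit = np.array(list(monomer * spec.monomers_per_hor))
    copies = []
    for _ in range(spec.n_hor_units):
        c = unit.copy()
        if spec.divergence_rate > 0:
            mask = rng.random(len(c)) < spec.divergence_rate
            idx = np.nonzero(mask)[0]
            for i in idx:
                alts = [b for b in "ACGT" if b != c[i]]
                c[i] = alts[rng.integers(3)]
        copies.append("".join(c))
    return "".join(copies)


def insert_dyads(
    seq: str,
    arm_length: int,
    spacer_length: int,
    count: int,
    seed: int,
    mirror: bool = False,
) -> tuple[str, list[tuple[int, int, int, int]]]:
    """Overwrite ``count`` two-armed repeats at non-overlapping positions.

    Each insertion is a random arm, a random spacer, and the arm's
    reverse complement (``mirror=False``) or its plain reversal
    (``mirror=True``).  Returns the new sequence and truth coordinates
    (start, end, arm_length, spacer_length).  Raises when the sequence
    cannot host ``count`` non-overlapping insertions.
    """
    if count == 0:
        return seq, []
    rng = np.random.default_rng(seed)
    motif_len = 2 * arm_length + spacer_length
    n = len(seq)
    if motif_len * count > n:
        raise ValueError("insufficient room for the requested insertions")
    placed: list[int] = []
    attempts = 0
    while len(placed) < count:
        attempts += 1
        if attempts > 1000 * count:
            raise ValueError("could not place non-overlapping insertions")
        pos = int(rng.integers(0, n - motif_len + 1))
        if all(abs(pos - q) >= motif_len for q in placed):
            placed.append(pos)
    placed.sort()
    arr = list(seq)
    truth = []
    for pos in placed:
        arm = _random_seq(rng, arm_length, 0.5)
        spacer = _random_seq(rng, spacer_length, 0.5)
        second = arm[::-1] if mirror else revcomp(arm)
        arr[pos:pos + motif_len] = list(arm + spacer + second)
        truth.append((pos, pos + motif_len, arm_length, spacer_length))
    return "".join(arr), truth


def _build_region(spec: SyntheticRegionSpec) -> tuple[str, list[dict]]:
    if spec.is_satellite:
        seq = make_hor_array(spec)
    else:
        rng = np.random.default_rng(spec.seed)
        seq = _random_seq(rng, spec.length, spec.gc_target)
    truth = []
    sub = spec.seed + 1
    for kind, insertions in (("inverted", spec.dyad_insertions),
                             ("mirror", spec.mirror_insertions)):
        for arm, spacer, count in insertions:
            seq, coords = insert_dyads(seq, arm, spacer, count, seed=sub,
                                       mirror=(kind == "mirror"))
            sub += 1
            for start, end, a, sp in coords:
                truth.append({"kind": kind, "start": start, "end": end,
                              "arm_length": a, "spacer_length": sp})
    return seq, truth


@dataclass
class SyntheticGenome:
    """In-memory fixture genome plus truth tables."""

    sequences: dict[str, str]
    intervals: list[GenomicInterval]
    repeat_truth: pd.DataFrame       # chrom, region_label, kind, start, end, arm, spacer
    region_truth: pd.DataFrame       # chrom, region_label, gc_target, start, end
    missegregation: pd.Series        # chrom -> probability

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "genome.fa"
        with fasta.open("w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
        bed = outdir / "regions.bed"
        with bed.open("w") as fh:
            for iv in self.intervals:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.region_label}\n")
        rt = outdir / "repeat_truth.tsv"
        self.repeat_truth.to_csv(rt, sep="\t", index=False)
        gt = outdir / "region_truth.tsv"
        self.region_truth.to_csv(gt, sep="\t", index=False)
        mt = outdir / "missegregation.tsv"
        self.missegregation.rename("probability").to_csv(mt, sep="\t",
                                                         index_label="chrom")
        return {"fasta": fasta, "bed": bed, "repeat_truth": rt,
                "region_truth": gt, "missegregation": mt}


def build_fixture_genome(
    region_specs: dict[str, list[SyntheticRegionSpec]],
    seed: int = 0,
) -> SyntheticGenome:
    """Assemble chromosomes by concatenating labeled regions.

    ``region_specs`` maps chromosome name to its ordered region specs
    (one per label at most).  Region seeds are combined with ``seed``
    so the whole genome is reproducible from one integer.
    """
    sequences: dict[str, str] = {}
    intervals: list[GenomicInterval] = []
    repeat_rows = []
    region_rows = []
    for ci, (chrom, specs) in enumerate(region_specs.items()):
        labels = [sp.region_label for sp in specs]
        if len(labels) != len(set(labels)):
            raise ValueError(f"{chrom}: duplicate region labels")
        parts: list[str] = []
        offset = 0
        for ri, sp in enumerate(specs):
            sp = replace(sp, seed=seed * 1_000_003 + ci * 1009 + ri * 17 + sp.seed)
            seq, truth = _build_region(sp)
            intervals.append(GenomicInterval(chrom, offset, offset + len(seq),
                                             sp.region_label))
            region_rows.append({"chrom": chrom, "region_label": sp.region_label,
                                "gc_target": sp.gc_target, "start": offset,
                                "end": offset + len(seq)})
            for t in truth:
                repeat_rows.append({"chrom": chrom, "region_label": sp.region_label,
                                    "kind": t["kind"],
                                    "start": offset + t["start"],
                                    "end": offset + t["end"],
                                    "arm_length": t["arm_length"],
                                    "spacer_length": t["spacer_length"]})
            parts.append(seq)
            offset += len(seq)
        sequences[chrom] = "".join(parts)
    rng = np.random.default_rng(seed + 777)
    chroms = list(region_specs)
    k = np.arange(len(chroms))
    probs = np.clip(0.30 - 0.03 * k + rng.normal(0, 0.01, len(chroms)), 0.0, 1.0)
    return SyntheticGenome(
        sequences=sequences,
        intervals=intervals,
        repeat_truth=pd.DataFrame(
            repeat_rows, columns=["chrom", "region_label", "kind", "start", "end",
                                  "arm_length", "spacer_length"]),
        region_truth=pd.DataFrame(
            region_rows, columns=["chrom", "region_label", "gc_target", "start", "end"]),
        missegregation=pd.Series(probs, index=chroms),
    )


def default_gradients_preset(
    seed: int = 0, n_chromosomes: int = 8
) -> dict[str, list[SyntheticRegionSpec]]:
    """The default study-conditions preset.

    Encodes the observed gradients: GC(centric transition) > GC(active
    HOR) > GC(divergent HOR); dyad density centric transition >
    divergent HOR > active HOR; coding ~0.52 GC with no inserted
    repeats; rDNA-like ~0.65 GC with mirror repeats (first five
    chromosomes, mimicking acrocentrics).  The last two chromosomes are
    the designed exclusions: one lacks a divergent array, one's
    divergent array is 3,420 nt (< 4,000).  A mild cross-chromosome GC
    and dyad-count gradient provides correlation signal with a known
    sign.
    """
    if n_chromosomes < 4:
        raise ValueError("preset needs at least 4 chromosomes")
    specs: dict[str, list[SyntheticRegionSpec]] = {}
    offsets = np.linspace(-0.04, 0.04, n_chromosomes)
    for k in range(n_chromosomes):
        chrom = f"chrS{k + 1}"
        off = float(offsets[k])
        regions: list[SyntheticRegionSpec] = [
            SyntheticRegionSpec(
                "active_hor", gc_target=0.40 + off, divergence_rate=0.02,
                dyad_insertions=((12, 8, 6 + k),),
            ),
            SyntheticRegionSpec(
                "divergent_hor", gc_target=0.36 + off, divergence_rate=0.12,
                dyad_insertions=((12, 8, 40 + 2 * k),),
            ),
            SyntheticRegionSpec(
                "centric_transition", gc_target=0.46 + off, length=24000,
                dyad_insertions=((12, 8, 90 + 3 * k),),
            ),
            SyntheticRegionSpec("coding", gc_target=0.52, length=24000),
        ]
        if k < 5:
            regions.append(SyntheticRegionSpec(
                "rdna", gc_target=0.65, length=20000,
                mirror_insertions=((15, 5, 20),),
            ))
        if k == n_chromosomes - 2:  # designed: no divergent array
            regions = [r for r in regions if r.region_label != "divergent_hor"]
        if k == n_chromosomes - 1:  # designed: divergent array < 4,000 nt
            regions = [
                replace(r, monomers_per_hor=20, n_hor_units=1,
                        dyad_insertions=((12, 8, 2),))
                if r.region_label == "divergent_hor" else r
                for r in regions
            ]
        specs[chrom] = regions
    return specs
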