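"""Nearest-neighbor free-energy parameters for single-stranded DNA folding.

The folding engine scores a secondary structure as a sum over loops
(stacks, hairpins, bulges, interior loops, multiloops) plus end
contributions.  All energies live in kcal/mol at a fixed 37 degC
(310.15 K); the tables are read from a parameter file in the ViennaRNA
2.x text dialect, whose integers are dekacal/mol (value / 100 kcal/mol).
Salt is treated as metadata baked into the parameter set, never as a
computed correction.

Pair encoding used throughout the package: bases N=0, A=1, C=2, G=3,
T=4; pair types 0=none, 1=CG, 2=GC, 3=GT, 4=TG, 5=AT, 6=TA, 7=NN.  A
pair type is *allowed* iff the loaded file gives it at least one finite
stack energy -- there is no hard-coded pairing alphabet, so a file with
finite G.T entries enables wobble pairs and the bundled default (which
marks them INF) does not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "EnergyParameters",
    "ParameterFileError",
    "load_parameters",
    "write_parameters",
    "default_parameter_path",
    "PAIR_NAMES",
    "BASE_CODE",
    "PAIR_INDEX",
    "GAS_CONSTANT_KCAL",
    "TEMPERATURE_K",
    "RT_KCAL",
]

GAS_CONSTANT_KCAL = 0.0019872  # kcal / (mol K)
TEMPERATURE_K = 310.15
RT_KCAL = GAS_CONSTANT_KCAL * TEMPERATURE_K  # 0.61633 kcal/mol

#: Row/column order of pair-indexed tables in the 2.x dialect.
PAIR_NAMES = ("NP", "CG", "GC", "GT", "TG", "AT", "TA", "NN")

BASE_CODE = {"N": 0, "A": 1, "C": 2, "G": 3, "T": 4}
_BASES = "NACGT"

#: (5' base, 3' base) -> pair type.
PAIR_INDEX = np.zeros((5, 5), dtype=np.int8)
for _pt, _pn in enumerate(PAIR_NAMES):
    if _pt in (0, 7):
        continue
    PAIR_INDEX[BASE_CODE[_pn[0]], BASE_CODE[_pn[1]]] = _pt

INF = float("inf")
_FILE_INF = "INF"
MAXLOOP = 30
#: Universal log-extrapolation coefficient for loops longer than MAXLOOP
#: (1.75 * RT at 37 degC).
LXC = 1.07856


class ParameterFileError(ValueError):
    """Raised when a parameter file is missing, unrecognized or truncated."""


@dataclass
class EnergyParameters:
    """Free-energy tables for the loop-based DNA model (kcal/mol, 37 degC).

    Tables indexed by pair type use axis length 8 (index 0 unused, 7 =
    the file's NN row); tables indexed by base use length 5 with N at 0.
    ``inf`` marks a forbidden (unparameterized) entry.
    """

    stack: np.ndarray            # (8, 8)
    terminal_mismatch: np.ndarray  # (8, 5, 5): [pair, 5' adjacent, 3' adjacent]
    dangle5: np.ndarray          # (8, 5)
    dangle3: np.ndarray          # (8, 5)
    hairpin: np.ndarray          # (31,) by loop size
    bulge: np.ndarray            # (31,)
    interior: np.ndarray         # (31,)
    ml_unpaired: float = 0.0
    ml_closing: float = 0.0
    ml_branch: float = 0.0
    ninio_slope: float = 0.0
    ninio_max: float = 3.0
    terminal_at: float = 0.0     # per helix end closed by an A.T (or wobble) pair
    duplex_init: float = 0.0     # metadata; not used in intramolecular folding
    gquad_stack_coeff: float = -18.0  # a in a*(L-1) + b*ln(ltot-2)
    gquad_linker_coeff: float = 12.0  # b
    lxc: float = LXC
    temperature: float = TEMPERATURE_K
    salt_label: str = "1.021 M NaCl"
    header: str = ""
    source: str = ""
    allowed_pairs: np.ndarray = field(default=None)  # (8,) bool

    def __post_init__(self) -> None:
        if self.temperature != TEMPERATURE_K:
            raise ValueError("model is defined at 310.15 K only")
        if self.allowed_pairs is None:
            allowed = np.zeros(8, dtype=bool)
            for pt in range(1, 7):
                allowed[pt] = bool(np.isfinite(self.stack[pt, 1:7]).any())
            self.allowed_pairs = allowed

    @property
    def rt(self) -> float:
        return RT_KCAL

    def pair_type(self, b5: int, b3: int) -> int:
        """Pair type of (5' base, 3' base) codes, 0 if never pairable."""
        pt = int(PAIR_INDEX[b5, b3])
        return pt if pt and self.allowed_pairs[pt] else 0

    def hairpin_energy_by_size(self, size: int) -> float:
        if size <= MAXLOOP:
            return float(self.hairpin[size])
        return float(self.hairpin[MAXLOOP]) + self.lxc * math.log(size / MAXLOOP)

    def bulge_energy_by_size(self, size: int) -> float:
        if size <= MAXLOOP:
            return float(self.bulge[size])
        return float(self.bulge[MAXLOOP]) + self.lxc * math.log(size / MAXLOOP)

    def interior_energy_by_size(self, size: int) -> float:
        if size <= MAXLOOP:
            return float(self.interior[size])
        return float(self.interior[MAXLOOP]) + self.lxc * math.log(size / MAXLOOP)

    def gquad_energy(self, layers: int, linker_total: int) -> float:
        """Energy of a four-run quadruplex: a*(L-1) + b*ln(ltot - 2).

        ``linker_total`` is the summed length of the three linkers
        (each 1..7, so the minimum of 3 gives a zero log term).
        """
        if linker_total < 3:
            raise ValueError("quadruplex linkers must total at least 3")
        return self.gquad_stack_coeff * (layers - 1) + self.gquad_linker_coeff * math.log(
            linker_total - 2
        )

    def validate(self) -> None:
        """Check the structural invariants of a loaded table set."""
        for name in ("hairpin", "bulge", "interior"):
            tab = getattr(self, name)
            finite = tab[np.isfinite(tab)]
            if (finite < 0).any():
                raise ParameterFileError(f"{name} table has negative loop penalties")
            tail = tab[4:]
            tail = tail[np.isfinite(tail)]
            if (np.diff(tail) < -1e-9).any():
                raise ParameterFileError(f"{name} table decreases beyond loop size 3")


def default_parameter_path() -> Path:
    """Path of the bundled unified DNA dG37 parameter file."""
    return Path(resources.files("satfold").joinpath("data/dna_unified_dg37.par"))


def _strip_comments(line: str) -> str:
    while "/*" in line:
        a = line.index("/*")
        b = line.find("*/", a + 2)
        line = line[:a] + (line[b + 2:] if b >= 0 else "")
    return line.strip()


def _to_kcal(tok: str, table: str, lineno: int) -> float:
    if tok.upper() == _FILE_INF:
        return INF
    try:
        return int(tok) / 100.0
    except ValueError as exc:
        raise ParameterFileError(
            f"bad value {tok!r} in table {table!r} at line {lineno}"
        ) from exc


def _read_values(lines, idx, n, table):
    """Collect exactly n numeric tokens starting at line index idx."""
    vals = []
    while len(vals) < n:
        if idx >= len(lines):
            raise ParameterFileError(
                f"table {table!r} truncated: expected {n} values, got {len(vals)}"
            )
        lineno, raw = lines[idx]
        text = _strip_comments(raw)
        if text.startswith("#"):
            raise ParameterFileError(
                f"table {table!r} truncated at line {lineno}: expected {n} values, got {len(vals)}"
            )
        for tok in text.split():
            vals.append(_to_kcal(tok, table, lineno))
        idx += 1
    if len(vals) > n:
        raise ParameterFileError(f"table {table!r} has {len(vals)} values, expected {n}")
    return vals, idx


def load_parameters(path: str | Path) -> EnergyParameters:
    """Load an EnergyParameters set from a ViennaRNA 2.x dialect file.

    File integers are dekacal/mol and are divided by 100 on ingest.  The
    sections this model consumes are ``stack``, ``mismatch_hairpin``
    (used as the terminal-mismatch table), ``dangle5``/``dangle3``,
    ``hairpin``/``bulge``/``internal``, ``ML_params``, ``NINIO``,
    ``Misc`` and an optional ``gquad`` extension; other sections
    (enthalpies, special interior-loop tables, tetraloop bonuses) are
    skipped.  Only ``stack`` is mandatory: missing end-contribution
    tables default to zero and missing loop tables stay forbidden
    (INF), so a minimal stack-only file loads but folds nothing.
    """
    path = Path(path)
    if not path.exists():
        raise ParameterFileError(f"parameter file not found: {path}")
    raw_lines = path.read_text().splitlines()
    if not raw_lines or not raw_lines[0].startswith("## RNAfold parameter file"):
        raise ParameterFileError(
            f"unrecognized parameter file header in {path}: expected "
            "'## RNAfold parameter file v2.0'"
        )
    header = raw_lines[0].strip()

    lines = [(i + 1, l) for i, l in enumerate(raw_lines)]
    # locate section headers
    sections: dict[str, int] = {}
    for idx, (lineno, raw) in enumerate(lines):
        text = raw.strip()
        if text.startswith("# "):
            sections.setdefault(text[2:].strip(), idx + 1)

    stack = np.full((8, 8), INF)
    mismatch = np.zeros((8, 5, 5))
    dangle5 = np.zeros((8, 5))
    dangle3 = np.zeros((8, 5))
    hairpin = np.full(31, INF)
    bulge = np.full(31, INF)
    interior = np.full(31, INF)
    ml = (0.0, 0.0, 0.0)
    ninio = (0.0, 3.0)
    term_at = 0.0
    duplex_init = 0.0
    gq = (-18.0, 12.0)

    if "stack" not in sections:
        raise ParameterFileError(f"no '# stack' section in {path}")
    vals, _ = _read_values(lines, sections["stack"], 49, "stack")
    stack[1:8, 1:8] = np.asarray(vals).reshape(7, 7)

    if "mismatch_hairpin" in sections:
        vals, _ = _read_values(lines, sections["mismatch_hairpin"], 7 * 25, "mismatch_hairpin")
        mismatch[1:8] = np.asarray(vals).reshape(7, 5, 5)
    for name, arr in (("dangle5", dangle5), ("dangle3", dangle3)):
        if name in sections:
            vals, _ = _read_values(lines, sections[name], 35, name)
            arr[1:8] = np.asarray(vals).reshape(7, 5)
    for name, arr in (("hairpin", hairpin), ("bulge", bulge), ("internal", interior)):
        if name in sections:
            vals, _ = _read_values(lines, sections[name], 31, name)
            arr[:] = vals
    if "ML_params" in sections:
        vals, _ = _read_values(lines, sections["ML_params"], 6, "ML_params")
        ml = (vals[0], vals[2], vals[4])  # unpaired, closing, branch (dH skipped)
    if "NINIO" in sections:
        vals, _ = _read_values(lines, sections["NINIO"], 3, "NINIO")
        ninio = (vals[0], vals[2])
    if "Misc" in sections:
        vals, _ = _read_values(lines, sections["Misc"], 4, "Misc")
        duplex_init, term_at = vals[0], vals[2]
    if "gquad" in sections:
        vals, _ = _read_values(lines, sections["gquad"], 2, "gquad")
        gq = (vals[0], vals[1])

    params = EnergyParameters(
        stack=stack,
        terminal_mismatch=mismatch,
        dangle5=dangle5,
        dangle3=dangle3,
        hairpin=hairpin,
        bulge=bulge,
        interior=interior,
        ml_unpaired=ml[0],
        ml_closing=ml[1],
        ml_branch=ml[2],
        ninio_slope=ninio[0],
        ninio_max=ninio[1],
        terminal_at=term_at,
        duplex_init=duplex_init,
        gquad_stack_coeff=gq[0],
        gquad_linker_coeff=gq[1],
        header=header,
        source=str(path),
    )
    params.validate()
    return params


def _fmt(v: float) -> str:
    return f"{_FILE_INF:>6}" if not np.isfinite(v) else f"{int(round(v * 100)):>6}"


def write_parameters(params: EnergyParameters, path: str | Path) -> None:
    """Write the held tables back in the 2.x dialect (round-trip safe)."""
    out = ["## RNAfold parameter file v2.0", ""]
    out.append("# stack")
    for r in range(1, 8):
        out.append(" ".join(_fmt(params.stack[r, c]) for c in range(1, 8)))
    out.append("")
    out.append("# mismatch_hairpin")
    for p in range(1, 8):
        for x in range(5):
            out.append(" ".join(_fmt(params.terminal_mismatch[p, x, y]) for y in range(5)))
    out.append("")
    for name, arr in (("dangle5", params.dangle5), ("dangle3", params.dangle3)):
        out.append(f"# {name}")
        for p in range(1, 8):
            out.append(" ".join(_fmt(arr[p, b]) for b in range(5)))
        out.append("")
    for name, arr in (("hairpin", params.hairpin), ("bulge", params.bulge),
                      ("internal", params.interior)):
        out.append(f"# {name}")
        for i in range(0, 31, 10):
            out.append(" ".join(_fmt(v) for v in arr[i:i + 10]))
        out.append("")
    out.append("# ML_params")
    out.append(" ".join(_fmt(v) for v in
                        (params.ml_unpaired, 0, params.ml_closing, 0, params.ml_branch, 0)))
    out.append("")
    out.append("# NINIO")
    out.append(" ".join(_fmt(v) for v in (params.ninio_slope, 0, params.ninio_max)))
    out.append("")
    out.append("# Misc")
    out.append(" ".join(_fmt(v) for v in (params.duplex_init, 0, params.terminal_at, 0)))
    out.append("")
    out.append("# gquad")
    out.append(" ".join(_fmt(v) for v in (params.gquad_stack_coeff, params.gquad_linker_coeff)))
    out.append("")
    out.append("#END")
    Path(path).write_text("\n".join(out) + "\n")
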