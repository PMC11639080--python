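"""DNA sequence container and encoding helpers.

Sequences are strings over {A, C, G, T, N} (uppercased on ingest; U is
rejected -- this package folds DNA, there is no RNA conversion).  The
numeric encoding N=0, A=1, C=2, G=3, T=4 matches the parameter tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import BASE_CODE

__all__ = ["NucleotideSequence", "encode", "decode", "revcomp", "clean_sequence"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_DECODE = "NACGT"
_VALID = frozenset("ACGTN")


def clean_sequence(seq: str) -> str:
    """Uppercase and validate; raise ValueError on empty or non-DNA input."""
    s = seq.upper()
    if not s:
        raise ValueError("empty sequence")
    bad = set(s) - _VALID
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    return s


def encode(seq: str) -> np.ndarray:
    """Encode a validated DNA string as int8 codes (N=0, A=1, C=2, G=3, T=4)."""
    s = clean_sequence(seq)
    return np.frombuffer(
        s.encode().translate(bytes.maketrans(b"NACGT", bytes(range(5)))), dtype=np.int8
    ).copy()


def decode(codes: np.ndarray) -> str:
    return "".join(_DECODE[c] for c in codes)


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class NucleotideSequence:
    """A DNA string with an identifier and optional source interval."""

    seq: str
    id: str = ""
    chrom: str = ""
    start: int = 0
    region_label: str = ""
    has_n: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        self.seq = clean_sequence(self.seq)
        self.has_n = "N" in self.seq

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def end(self) -> int:
        return self.start + len(self.seq)
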