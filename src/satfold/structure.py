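"""Secondary-structure representation and dot-bracket serialization.

A structure is a pseudoknot-free set of base pairs (i, j), i < j,
0-based, with hairpin loops of at least 3 unpaired bases (j - i >= 4).
Quadruplex runs detected by the folding engine are not base pairs; they
are carried separately and rendered as '+' in dot-bracket strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["SecondaryStructure", "StructureError"]

MIN_HAIRPIN = 3


class StructureError(ValueError):
    """Raised for structures violating the pairing rules."""


@dataclass(frozen=True)
class SecondaryStructure:
    """An ordered, validated set of base pairs on a sequence of given length."""

    length: int
    pairs: tuple[tuple[int, int], ...] = ()
    gquads: tuple[tuple[int, int, int], ...] = ()  # (start, end exclusive, layers)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(sorted(tuple(p) for p in self.pairs)))
        object.__setattr__(self, "gquads", tuple(sorted(self.gquads)))
        self._validate()

    def _validate(self) -> None:
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < self.length):
                raise StructureError(f"pair ({i},{j}) out of bounds for length {self.length}")
            if j - i < MIN_HAIRPIN + 1:
                raise StructureError(f"pair ({i},{j}) closes a hairpin with < 3 unpaired bases")
            if i in seen or j in seen:
                raise StructureError(f"base in more than one pair at ({i},{j})")
            seen.add(i)
            seen.add(j)
        plist = self.pairs
        for a in range(len(plist)):
            i, j = plist[a]
            for b in range(a + 1, len(plist)):
                k, l = plist[b]
                if k > j:
                    break
                if i < k < j < l:
                    raise StructureError(f"pseudoknot: ({i},{j}) crosses ({k},{l})")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def partner(self) -> dict[int, int]:
        d: dict[int, int] = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d

    def is_canonical(self) -> bool:
        """True iff every pair stacks on an adjacent pair (no lonely pairs)."""
        ps = set(self.pairs)
        return all((i + 1, j - 1) in ps or (i - 1, j + 1) in ps for i, j in ps)

    def to_dotbracket(self) -> str:
        s = ["."] * self.length
        for i, j in self.pairs:
            s[i] = "("
            s[j] = ")"
        for a, b, _layers in self.gquads:
            for k in range(a, b):
                s[k] = "+"
        return "".join(s)

    @classmethod
    def from_dotbracket(cls, db: str) -> "SecondaryStructure":
        stack: list[int] = []
        pairs: list[tuple[int, int]] = []
        gq: list[int] = []
        for idx, ch in enumerate(db):
            if ch == "(":
                stack.append(idx)
            elif ch == ")":
                if not stack:
                    raise StructureError(f"unbalanced ')' at {idx}")
                pairs.append((stack.pop(), idx))
            elif ch == "+":
                gq.append(idx)
            elif ch != ".":
                raise StructureError(f"bad dot-bracket character {ch!r} at {idx}")
        if stack:
            raise StructureError(f"unbalanced '(' at {stack[-1]}")
        gquads: list[tuple[int, int, int]] = []
        if gq:
            run_start = gq[0]
            prev = gq[0]
            for k in gq[1:] + [None]:
                if k is None or k != prev + 1:
                    gquads.append((run_start, prev + 1, 0))
                    if k is not None:
                        run_start = k
                prev = k if k is not None else prev
        return cls(length=len(db), pairs=tuple(pairs), gquads=tuple(gquads))

    def base_pair_distance(self, other: "SecondaryStructure") -> int:
        """Symmetric-difference distance between two pair sets."""
        return len(set(self.pairs) ^ set(other.pairs))
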