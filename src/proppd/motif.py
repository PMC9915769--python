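"""Degenerate short-linear-motif patterns.

A motif such as ``PxYx[IL]`` is a fixed-length pattern in which each
position is either a fixed residue (``P``), a small allowed-residue set
(``[IL]``) or a wildcard (``x``) that matches any amino acid.  Patterns of
this shape are the lingua franca of SLiM biology: the pattern discovered by
phage display against the OGT intervening domain, ``PxYx[I/L]``, reads
"proline, anything, tyrosine, anything, isoleucine-or-leucine".
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

_TOKEN = re.compile(r"\[([A-Z]+)\]|([A-Z])|(x)")


@dataclass(frozen=True)
class DegenerateMotif:
    """A fixed-length degenerate pattern over the 20 amino acids.

    ``positions[i]`` is a frozenset of allowed residues, or ``None`` for a
    wildcard position.  The first and last positions must be fixed (no
    dangling wildcards), matching how SLiM patterns are conventionally
    written.
    """

    positions: tuple[frozenset | None, ...]

    def __post_init__(self) -> None:
        if len(self.positions) < 1:
            raise ValueError("empty motif")
        if self.positions[0] is None or self.positions[-1] is None:
            raise ValueError("motif may not start or end with a wildcard")
        for p in self.positions:
            if p is not None:
                if not p or not p <= _AA_SET:
                    raise ValueError(f"invalid residue set {set(p)!r}")

    # -- constructors -------------------------------------------------

    @classmethod
    def parse(cls, pattern: str) -> "DegenerateMotif":
        """Parse a pattern string like ``"PxYx[IL]"``."""
        positions: list[frozenset | None] = []
        pos = 0
        while pos < len(pattern):
            m = _TOKEN.match(pattern, pos)
            if m is None:
                raise ValueError(f"cannot parse motif pattern {pattern!r} at {pos}")
            group, single, wild = m.groups()
            if wild is not None:
                positions.append(None)
            elif single is not None:
                positions.append(frozenset(single))
            else:
                positions.append(frozenset(group))
            pos = m.end()
        return cls(tuple(positions))

    # -- formatting ---------------------------------------------------

    @property
    def pattern(self) -> str:
        """Canonical pattern string; residue sets are alphabetised."""
        out = []
        for p in self.positions:
            if p is None:
                out.append("x")
            elif len(p) == 1:
                out.append(next(iter(p)))
            else:
                out.append("[" + "".join(sorted(p)) + "]")
        return "".join(out)

    def __str__(self) -> str:
        return self.pattern

    # -- basic properties ---------------------------------------------

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_fixed(self) -> int:
        return sum(1 for p in self.positions if p is not None)

    @property
    def tyr_offset(self) -> int | None:
        """0-based offset of a fixed, unambiguous Y at motif position 3.

        The motif tyrosine is the pTyr-crosstalk anchor for ``PxYx[IL]``-style
        patterns; ``None`` when position 3 is absent or is not exactly {Y}.
        """
        if len(self.positions) < 3:
            return None
        return 2 if self.positions[2] == frozenset("Y") else None

    # -- matching -----------------------------------------------------

    def to_regex(self) -> str:
        parts = []
        for p in self.positions:
            if p is None:
                parts.append(f"[{AMINO_ACIDS}]")
            else:
                parts.append("[" + "".join(sorted(p)) + "]")
        return "".join(parts)

    def _compiled(self) -> re.Pattern:
        # overlapping matches via lookahead
        return re.compile(f"(?=({self.to_regex()}))")

    def finditer(self, sequence: str) -> Iterator[int]:
        """Yield 0-based start positions of all (overlapping) matches."""
        for m in self._compiled().finditer(sequence):
            yield m.start()

    def match_starts(self, sequence: str) -> list[int]:
        return list(self.finditer(sequence))

    def matches(self, sequence: str) -> bool:
        """True if the sequence contains at least one match."""
        return re.search(self.to_regex(), sequence) is not None

    def matches_at(self, sequence: str, start: int) -> bool:
        """Position-by-position check at a 0-based start (no regex)."""
        if start < 0 or start + len(self) > len(sequence):
            return False
        for off, p in enumerate(self.positions):
            res = sequence[start + off]
            if p is None:
                if res not in _AA_SET:
                    return False
            elif res not in p:
                return False
        return True

    def matches_with_variants(self, sequence: str, max_mismatch: int = 1) -> bool:
        """Match allowing up to ``max_mismatch`` fixed positions to disagree.

        Implements "this exact motif or a single amino acid variant"
        counting: a window matches when at most ``max_mismatch`` of the
        fixed positions hold a disallowed residue.
        """
        n = len(self)
        for start in range(len(sequence) - n + 1):
            mism = 0
            ok = True
            for off, p in enumerate(self.positions):
                if p is None:
                    continue
                if sequence[start + off] not in p:
                    mism += 1
                    if mism > max_mismatch:
                        ok = False
                        break
            if ok:
                return True
        return False

    def site_probability(self, background: dict[str, float]) -> float:
        """P(random window matches) under an i.i.d. residue background."""
        p = 1.0
        for pos in self.positions:
            if pos is None:
                continue
            p *= sum(background.get(a, 0.0) for a in pos)
        return p


def uniform_background() -> dict[str, float]:
    """Uniform residue frequencies (1/20 each)."""
    return {a: 1.0 / 20.0 for a in AMINO_ACIDS}
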