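"""Breakend (BND) ALT parsing and mate pairing.

A breakend ALT encodes one side of a novel adjacency in one of exactly four
bracket patterns::

    t[p[   piece extending right of this breakpoint joins sequence starting at p
    t]p]   ... joins the reverse complement ending at p
    ]p]t   piece extending left joins sequence ending at p
    [p[t   ... joins the reverse complement starting at p

Mates are identified first by MATEID cross-references, then greedily by
positional coordinates within a configurable tolerance (default 3 bp).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Optional, Sequence


class Orientation(enum.Enum):
    T_BRACKET_RIGHT = "t[p["
    T_BRACKET_LEFT = "t]p]"
    BRACKET_LEFT_T = "]p]t"
    BRACKET_RIGHT_T = "[p[t"


#: strand pair conventionally implied by each single-half orientation
ORIENTATION_STRANDS = {
    Orientation.T_BRACKET_RIGHT: "+-",
    Orientation.T_BRACKET_LEFT: "++",
    Orientation.BRACKET_LEFT_T: "--",
    Orientation.BRACKET_RIGHT_T: "-+",
}


class BreakendParseError(ValueError):
    """ALT allele does not match the VCF breakend grammar."""


@dataclass
class BreakendHalf:
    record_id: str
    chrom: str
    pos: int
    mate_chrom: str
    mate_pos: int
    orientation: Orientation
    inserted_seq: str = ""
    mate_id: Optional[str] = None


@dataclass
class MatePairing:
    first: BreakendHalf
    second: BreakendHalf
    evidence: str  # "mate_id" | "positional"
    tolerance_used: int = 0


_BND_RE = re.compile(
    r"^(?P<left>[A-Za-z.*]*)"
    r"(?P<open>[\[\]])(?P<chrom>[^:\[\]]+):(?P<pos>\d+)(?P<close>[\[\]])"
    r"(?P<right>[A-Za-z.*]*)$"
)


def parse_breakend(
    alt_allele: str,
    chrom: str,
    pos: int,
    record_id: str = "",
    mate_id: Optional[str] = None,
) -> BreakendHalf:
    """Parse one breakend ALT into its orientation and mate coordinates."""
    m = _BND_RE.match(alt_allele)
    if m is None or m.group("open") != m.group("close"):
        raise BreakendParseError(f"not a breakend ALT: {alt_allele!r}")
    left, right = m.group("left"), m.group("right")
    if bool(left) == bool(right):
        raise BreakendParseError(f"breakend ALT needs anchor base on exactly one side: {alt_allele!r}")
    bracket = m.group("open")
    if left:
        orientation = Orientation.T_BRACKET_RIGHT if bracket == "[" else Orientation.T_BRACKET_LEFT
        inserted = left[1:]
    else:
        orientation = Orientation.BRACKET_LEFT_T if bracket == "]" else Orientation.BRACKET_RIGHT_T
        inserted = right[:-1]
    return BreakendHalf(
        record_id=record_id,
        chrom=chrom,
        pos=pos,
        mate_chrom=m.group("chrom"),
        mate_pos=int(m.group("pos")),
        orientation=orientation,
        inserted_seq=inserted,
        mate_id=mate_id,
    )


def _cross_distance(a: BreakendHalf, b: BreakendHalf) -> Optional[int]:
    """Summed positional mismatch if a/b could be mates, else None."""
    if a.mate_chrom != b.chrom or b.mate_chrom != a.chrom:
        return None
    return abs(a.mate_pos - b.pos) + abs(b.mate_pos - a.pos)


def _within(a: BreakendHalf, b: BreakendHalf, tolerance: int) -> bool:
    if a.mate_chrom != b.chrom or b.mate_chrom != a.chrom:
        return False
    return abs(a.mate_pos - b.pos) <= tolerance and abs(b.mate_pos - a.pos) <= tolerance


def pair_mates(
    halves: Sequence[BreakendHalf],
    tolerance: int = 3,
) -> tuple[list[MatePairing], list[BreakendHalf]]:
    """Pair breakend halves into junctions.

    MATEID cross-references take priority; remaining halves are paired
    greedily by smallest summed cross-distance within *tolerance* (ties by
    input order). Each half joins at most one pairing; leftover halves are
    returned unpaired.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    used = [False] * len(halves)
    by_id = {}
    for i, h in enumerate(halves):
        by_id.setdefault(h.record_id, i)
    pairings: list[MatePairing] = []

    # pass 1: MATEID evidence
    for i, h in enumerate(halves):
        if used[i] or not h.mate_id:
            continue
        j = by_id.get(h.mate_id)
        if j is None or j == i or used[j]:
            continue
        used[i] = used[j] = True
        pairings.append(MatePairing(h, halves[j], evidence="mate_id"))

    # pass 2: greedy positional pairing
    candidates = []
    for i in range(len(halves)):
        if used[i]:
            continue
        for j in range(i + 1, len(halves)):
            if used[j]:
                continue
            if _within(halves[i], halves[j], tolerance):
                d = _cross_distance(halves[i], halves[j])
                candidates.append((d, i, j))
    for d, i, j in sorted(candidates, key=lambda t: (t[0], t[1], t[2])):
        if used[i] or used[j]:
            continue
        used[i] = used[j] = True
        pairings.append(
            MatePairing(halves[i], halves[j], evidence="positional", tolerance_used=tolerance)
        )
    unpaired = [h for i, h in enumerate(halves) if not used[i]]
    return pairings, unpaired
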