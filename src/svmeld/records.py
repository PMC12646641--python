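"""Normalized structural-variant record model.

Coordinates are kept 1-based and fully closed, exactly as VCF prints them;
interval arithmetic converts to half-open only inside overlap computations.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional


class SVType(str, enum.Enum):
    DEL = "DEL"
    INS = "INS"
    INV = "INV"
    DUP = "DUP"
    TRA = "TRA"
    BND = "BND"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Orientation pair of the two breakpoints. ``.`` means unknown.
STRAND_PAIRS = ("++", "+-", "-+", "--", "..")

# canonical strand pair implied by each simple SV type
TYPE_STRANDS = {SVType.DEL: "+-", SVType.DUP: "-+"}


@dataclass
class GenotypeCall:
    """One sample's call: diploid GT plus optional AD/DP/GQ."""

    gt: str = "./."
    ad: Optional[tuple[int, int]] = None  # (ref_reads, variant_reads)
    dp: Optional[int] = None
    gq: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ad is not None:
            if len(self.ad) != 2 or any(x < 0 for x in self.ad):
                raise ValueError(f"AD must be a pair of non-negative ints, got {self.ad!r}")
            self.ad = (int(self.ad[0]), int(self.ad[1]))

    @property
    def variant_reads(self) -> Optional[int]:
        return None if self.ad is None else self.ad[1]


@dataclass
class SVRecord:
    """One normalized SV call (canonical type or unresolved BND).

    ``pos``/``end`` are 1-based closed. ``chrom2``/``pos2`` carry the second
    breakpoint for inter-chromosomal events (TRA and cross-chromosome BND).
    ``info`` holds residual, string-valued tags not covered by typed fields.
    """

    record_id: str
    chrom: str
    pos: int
    svtype: SVType
    end: Optional[int] = None
    svlen: Optional[int] = None
    chrom2: Optional[str] = None
    pos2: Optional[int] = None
    strands: str = ".."
    ref_allele: str = "N"
    alt_allele: str = ""
    qual: Optional[float] = None
    filter: str = "PASS"
    info: dict[str, str] = field(default_factory=dict)
    samples: dict[str, GenotypeCall] = field(default_factory=dict)
    source_caller: str = ""
    source_file: str = ""

    def __post_init__(self) -> None:
        if isinstance(self.svtype, str):
            self.svtype = SVType(self.svtype)
        if self.pos < 1:
            raise ValueError(f"{self.record_id}: pos must be >= 1, got {self.pos}")
        if self.strands not in STRAND_PAIRS:
            raise ValueError(f"{self.record_id}: bad strand pair {self.strands!r}")
        if self.svtype in (SVType.TRA, SVType.BND):
            if self.svtype is SVType.TRA and (self.chrom2 is None or self.pos2 is None):
                raise ValueError(f"{self.record_id}: TRA requires chrom2/pos2")
        else:
            if self.chrom2 is not None and self.chrom2 != self.chrom:
                raise ValueError(
                    f"{self.record_id}: chrom2 only valid for TRA/BND, got {self.chrom2}"
                )
            if self.end is not None and self.end < self.pos:
                raise ValueError(f"{self.record_id}: end {self.end} < pos {self.pos}")

    # -- derived quantities -------------------------------------------------

    @property
    def size(self) -> Optional[int]:
        """Event size in bp (|SVLEN|, or END-POS when SVLEN is absent)."""
        if self.svlen is not None:
            return abs(self.svlen)
        if self.end is not None and self.svtype not in (SVType.TRA, SVType.BND):
            return self.end - self.pos
        return None

    def interval(self) -> tuple[int, int]:
        """Half-open genomic interval [pos, end) for overlap math."""
        end = self.end if self.end is not None else self.pos
        return (self.pos, max(end, self.pos))

    def breakpoints(self) -> tuple[tuple[str, int], tuple[str, int]]:
        """Both breakpoints, canonically ordered for inter-chromosomal events."""
        if self.chrom2 is not None and self.pos2 is not None:
            a, b = (self.chrom, self.pos), (self.chrom2, self.pos2)
            return (a, b) if a <= b else (b, a)
        return ((self.chrom, self.pos), (self.chrom, self.end or self.pos))

    def first_genotype(self) -> Optional[GenotypeCall]:
        for call in self.samples.values():
            return call
        return None

    @property
    def variant_reads(self) -> Optional[int]:
        call = self.first_genotype()
        return None if call is None else call.variant_reads

    def copy(self, **changes) -> "SVRecord":
        rec = replace(self, **changes)
        rec.info = dict(changes.get("info", self.info))
        rec.samples = {k: replace(v) for k, v in changes.get("samples", self.samples).items()}
        return rec


def normalize_len_end(rec: SVRecord) -> SVRecord:
    """Fill missing SVLEN from END-POS (and vice versa) for DEL/DUP/INV.

    DEL gets negative SVLEN by convention. Raises ValueError when both are
    missing for a type that needs them.
    """
    if rec.svtype not in (SVType.DEL, SVType.DUP, SVType.INV):
        return rec
    if rec.end is None and rec.svlen is None:
        raise ValueError(f"{rec.record_id}: {rec.svtype} lacks both END and SVLEN")
    if rec.svlen is None:
        span = rec.end - rec.pos
        rec.svlen = -span if rec.svtype is SVType.DEL else span
    if rec.end is None:
        rec.end = rec.pos + abs(rec.svlen)
    return rec


def jaccard(a: SVRecord, b: SVRecord) -> float:
    """Interval Jaccard index (intersection/union of half-open spans)."""
    a0, a1 = a.interval()
    b0, b1 = b.interval()
    inter = max(0, min(a1, b1) - max(a0, b0))
    union = (a1 - a0) + (b1 - b0) - inter
    return inter / union if union > 0 else 0.0


def strands_consistent(a: str, b: str) -> bool:
    """Unknown strands ('..') are consistent with anything."""
    return a == ".." or b == ".." or a == b
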