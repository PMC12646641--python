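"""Hierarchical BND correction: convert breakend pairs to canonical SV types.

Same-chromosome junctions are classified by bracket-orientation topology:

====  =============================  ====================================
type  left half (L)                  right half (R)
====  =============================  ====================================
DEL   ``t[p[`` pointing to R         ``]p]t`` pointing back to L
DUP   ``]p]t`` whose mate is R       ``t[p[`` whose mate is L
INV   ``t]p]`` on both halves, or ``[p[t`` on both halves
====  =============================  ====================================

These are the only junction topologies consistent with each canonical type:
a forward-strand junction that skips an interval deletes it, a junction
running 3'→5' back across the span is a tandem duplication, and same-side
bracket pairs imply a strand flip (inversion). Anything else — and any pair
spanning less than the minimum SV size — is retained as BND to respect the
uncertainty of the original call. Cross-chromosome junctions become TRA
records subtyped balanced (reciprocal exchange), unbalanced (one-way
transfer), or merging (duplicate representations of one junction collapsed).
BNDs are never converted to INS: insertion calling needs sequence content
that breakpoint coordinates cannot supply.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .breakends import (
    BreakendHalf,
    BreakendParseError,
    MatePairing,
    Orientation,
    ORIENTATION_STRANDS,
    pair_mates,
    parse_breakend,
)
from .records import SVRecord, SVType

__all__ = ["AuditEntry", "CorrectionResult", "correct", "classify_same_chrom_pair"]

#: minimum same-chromosome span (bp) to call a canonical SV from a BND pair
MIN_SPAN = 50


@dataclass
class AuditEntry:
    input_id: str
    action: str  # pass_through | converted | retained | collapsed
    rule: str
    evidence: str = ""
    output_id: str = ""


@dataclass
class CorrectionResult:
    corrected: list[SVRecord] = field(default_factory=list)
    retained_bnd: list[SVRecord] = field(default_factory=list)
    audit: list[AuditEntry] = field(default_factory=list)

    @property
    def all_records(self) -> list[SVRecord]:
        return self.corrected + self.retained_bnd


def _retained_side(orientation: Orientation) -> str:
    """Which side of its breakpoint a half keeps: 5' (anchor before bracket)
    or 3' (anchor after)."""
    if orientation in (Orientation.T_BRACKET_RIGHT, Orientation.T_BRACKET_LEFT):
        return "5'"
    return "3'"


def classify_same_chrom_pair(pair: MatePairing) -> Optional[SVType]:
    """Apply the same-chromosome decision table; None means retain as BND."""
    left, right = pair.first, pair.second
    if left.pos > right.pos:
        left, right = right, left
    lo, ro = left.orientation, right.orientation
    if lo is Orientation.T_BRACKET_RIGHT and ro is Orientation.BRACKET_LEFT_T:
        return SVType.DEL
    if lo is Orientation.BRACKET_LEFT_T and ro is Orientation.T_BRACKET_RIGHT:
        return SVType.DUP
    if lo is ro and lo in (Orientation.T_BRACKET_LEFT, Orientation.BRACKET_RIGHT_T):
        return SVType.INV
    return None


def _pick_genotype_source(
    halves: Sequence[BreakendHalf], by_id: dict[str, SVRecord]
) -> SVRecord:
    """Half with the highest variant AD wins; fall back to the first half."""
    best, best_ad = None, -1
    for h in halves:
        rec = by_id[h.record_id]
        ad = rec.variant_reads
        if ad is not None and ad > best_ad:
            best, best_ad = rec, ad
    return best if best is not None else by_id[halves[0].record_id]


class _Corrector:
    def __init__(self, tolerance: int, min_span: int):
        self.tolerance = tolerance
        self.min_span = min_span
        self.result = CorrectionResult()
        self._counter = 0

    def _new_id(self, svtype: SVType) -> str:
        self._counter += 1
        return f"svmeld_{svtype.value}_{self._counter}"

    def _emit(self, rec: SVRecord) -> None:
        self.result.corrected.append(rec)

    def _retain(self, rec: SVRecord, rule: str, evidence: str = "") -> None:
        self.result.retained_bnd.append(rec)
        self.result.audit.append(
            AuditEntry(rec.record_id, "retained", rule, evidence, rec.record_id)
        )

    # -- same-chromosome ----------------------------------------------------

    def classify_same_chrom(self, pair: MatePairing, by_id: dict[str, SVRecord]) -> None:
        left, right = pair.first, pair.second
        if left.pos > right.pos:
            left, right = right, left
        span = right.pos - left.pos
        ids = (pair.first.record_id, pair.second.record_id)
        if span < self.min_span:
            for rid in ids:
                self._retain(by_id[rid], "below_min_span", f"span={span}")
            return
        svtype = classify_same_chrom_pair(pair)
        if svtype is None:
            for rid in ids:
                self._retain(
                    by_id[rid],
                    "complex_orientation",
                    f"{left.orientation.value}/{right.orientation.value}",
                )
            return
        source = _pick_genotype_source([pair.first, pair.second], by_id)
        if svtype is SVType.DEL:
            svlen, strands = -span, "+-"
        elif svtype is SVType.DUP:
            svlen, strands = span, "-+"
        else:
            svlen = span
            strands = "++" if left.orientation is Orientation.T_BRACKET_LEFT else "--"
        out = SVRecord(
            record_id=self._new_id(svtype),
            chrom=left.chrom,
            pos=left.pos,
            svtype=svtype,
            end=right.pos,
            svlen=svlen,
            strands=strands,
            ref_allele="N",
            alt_allele=f"<{svtype.value}>",
            qual=source.qual,
            filter=source.filter,
            samples={k: v for k, v in source.samples.items()},
            source_caller=source.source_caller,
            source_file=source.source_file,
        )
        self._emit(out)
        for rid in ids:
            self.result.audit.append(
                AuditEntry(rid, "converted", f"same_chrom_{svtype.value}",
                           pair.evidence, out.record_id)
            )

    # -- cross-chromosome ---------------------------------------------------

    def _tra_from_pairing(
        self, pair: MatePairing, by_id: dict[str, SVRecord], subtype: str,
        extra_ids: Sequence[str] = (),
    ) -> SVRecord:
        a, b = pair.first, pair.second
        if (a.chrom, a.pos) > (b.chrom, b.pos):
            a, b = b, a
        source = _pick_genotype_source([pair.first, pair.second], by_id)
        strands = ORIENTATION_STRANDS[a.orientation]
        out = SVRecord(
            record_id=self._new_id(SVType.TRA),
            chrom=a.chrom,
            pos=a.pos,
            svtype=SVType.TRA,
            chrom2=b.chrom,
            pos2=b.pos,
            strands=strands,
            ref_allele="N",
            alt_allele="<TRA>",
            qual=source.qual,
            filter=source.filter,
            info={"SUBTYPE": subtype},
            samples={k: v for k, v in source.samples.items()},
            source_caller=source.source_caller,
            source_file=source.source_file,
        )
        self._emit(out)
        for rid in (pair.first.record_id, pair.second.record_id):
            self.result.audit.append(
                AuditEntry(rid, "converted", f"cross_chrom_{subtype}",
                           pair.evidence, out.record_id)
            )
        for rid in extra_ids:
            self.result.audit.append(
                AuditEntry(rid, "collapsed", "merging_duplicate_junction",
                           "positional", out.record_id)
            )
        return out

    def _canonical_coords(self, pair: MatePairing):
        a, b = pair.first, pair.second
        if (a.chrom, a.pos) > (b.chrom, b.pos):
            a, b = b, a
        return a, b

    def classify_cross_chrom(
        self,
        pairs: Sequence[MatePairing],
        unpaired: Sequence[BreakendHalf],
        by_id: dict[str, SVRecord],
    ) -> None:
        # group by unordered chromosome pair
        groups: dict[tuple[str, str], list[MatePairing]] = {}
        for p in pairs:
            a, b = self._canonical_coords(p)
            groups.setdefault((a.chrom, b.chrom), []).append(p)

        for group in groups.values():
            consumed = [False] * len(group)
            subtype = ["unbalanced"] * len(group)
            merged_into: dict[int, list[str]] = {}
            for i in range(len(group)):
                if consumed[i]:
                    continue
                ai, bi = self._canonical_coords(group[i])
                for j in range(i + 1, len(group)):
                    if consumed[j]:
                        continue
                    aj, bj = self._canonical_coords(group[j])
                    close = (
                        abs(ai.pos - aj.pos) <= self.tolerance
                        and abs(bi.pos - bj.pos) <= self.tolerance
                    )
                    if not close:
                        continue
                    same_sides = (
                        ai.orientation is aj.orientation
                        and bi.orientation is bj.orientation
                    )
                    complementary = (
                        _retained_side(ai.orientation) != _retained_side(aj.orientation)
                        and _retained_side(bi.orientation) != _retained_side(bj.orientation)
                    )
                    if same_sides:
                        # duplicate evidence for one junction
                        consumed[j] = True
                        merged_into.setdefault(i, []).extend(
                            (group[j].first.record_id, group[j].second.record_id)
                        )
                        subtype[i] = "merging"
                    elif complementary and subtype[i] == "unbalanced":
                        subtype[i] = subtype[j] = "balanced"
            for i, p in enumerate(group):
                if consumed[i]:
                    continue
                self._tra_from_pairing(p, by_id, subtype[i], merged_into.get(i, ()))

        for half in unpaired:
            rec = by_id[half.record_id]
            a = (half.chrom, half.pos)
            b = (half.mate_chrom, half.mate_pos)
            swapped = a > b
            if swapped:
                a, b = b, a
            strands = ORIENTATION_STRANDS[half.orientation]
            if swapped:
                strands = strands[::-1]
            out = SVRecord(
                record_id=self._new_id(SVType.TRA),
                chrom=a[0],
                pos=a[1],
                svtype=SVType.TRA,
                chrom2=b[0],
                pos2=b[1],
                strands=strands,
                ref_allele="N",
                alt_allele="<TRA>",
                qual=rec.qual,
                filter=rec.filter,
                info={"SUBTYPE": "unbalanced"},
                samples={k: v for k, v in rec.samples.items()},
                source_caller=rec.source_caller,
                source_file=rec.source_file,
            )
            self._emit(out)
            self.result.audit.append(
                AuditEntry(half.record_id, "converted", "cross_chrom_unbalanced",
                           "no_mate", out.record_id)
            )


def correct(
    records: Sequence[SVRecord],
    tolerance: int = 3,
    min_span: int = MIN_SPAN,
) -> CorrectionResult:
    """Convert BND records to canonical SV types where the junction topology
    is unambiguous; retain the rest.

    Non-BND records pass through untouched. The audit covers every input
    record exactly once.
    """
    worker = _Corrector(tolerance, min_span)
    result = worker.result
    by_id: dict[str, SVRecord] = {}
    same_chrom: list[BreakendHalf] = []
    cross_chrom: list[BreakendHalf] = []

    for idx, rec in enumerate(records):
        if rec.svtype is not SVType.BND:
            result.corrected.append(rec)
            result.audit.append(
                AuditEntry(rec.record_id, "pass_through", "non_bnd", "", rec.record_id)
            )
            continue
        uid = rec.record_id if rec.record_id not in by_id else f"{rec.record_id}#{idx}"
        by_id[uid] = rec
        try:
            half = parse_breakend(
                rec.alt_allele, rec.chrom, rec.pos,
                record_id=uid, mate_id=rec.info.get("MATEID") or None,
            )
        except BreakendParseError as exc:
            worker._retain(rec, "unparseable", str(exc))
            continue
        (same_chrom if half.chrom == half.mate_chrom else cross_chrom).append(half)

    pairs_sc, unpaired_sc = pair_mates(same_chrom, tolerance)
    for pair in pairs_sc:
        worker.classify_same_chrom(pair, by_id)
    for half in unpaired_sc:
        worker._retain(by_id[half.record_id], "no_mate_same_chrom")

    pairs_cc, unpaired_cc = pair_mates(cross_chrom, tolerance)
    worker.classify_cross_chrom(pairs_cc, unpaired_cc, by_id)
    return result
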