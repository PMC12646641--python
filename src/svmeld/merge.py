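"""Cluster equivalent SV calls across callers/samples and resolve genotypes.

Two non-TRA calls of the same type match when their start and end coordinates
agree within ``max_distance``, their sizes agree within ``max_size_ratio``,
and their interval Jaccard index reaches ``min_jaccard`` (the Jaccard test is
waived for point-like insertions). TRA calls match on both breakpoints within
``tra_distance`` on the same chromosome pair with consistent strands. Records
are then partitioned into connected components of the pairwise-match graph
within each (svtype, chromosome-pair) bucket; each component becomes one
consensus record carrying its supporting-caller set.

Conflicting genotypes are resolved hierarchically: majority vote among
callers, then highest variant-supporting read count (AD), then caller input
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .records import GenotypeCall, SVRecord, SVType, jaccard, strands_consistent

__all__ = [
    "MergeParams",
    "MergedRecord",
    "FilterReport",
    "pairwise_match",
    "cluster",
    "resolve_genotype",
    "quality_filter",
]


@dataclass
class MergeParams:
    """Matching thresholds for the merge step.

    max_distance: breakpoint distance for non-TRA start/end matching (bp);
        the useful range is roughly 50-150, default 50 (strictest).
    max_size_ratio: largest allowed size ratio max/min between members.
    min_jaccard: minimum interval Jaccard index (intersection/union).
    tra_distance: more permissive breakpoint distance for translocations.
    require_strand_match_tra: demand consistent strand pairs for TRA
        (records with unknown strands are consistent with anything).
    """

    max_distance: int = 50
    max_size_ratio: float = 1.3
    min_jaccard: float = 0.7
    tra_distance: int = 500
    require_strand_match_tra: bool = True

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ValueError("max_distance must be > 0")
        if self.max_size_ratio < 1:
            raise ValueError("max_size_ratio must be >= 1")
        if not (0 < self.min_jaccard <= 1):
            raise ValueError("min_jaccard must be in (0, 1]")


@dataclass
class MergedRecord:
    representative: SVRecord
    members: list[SVRecord]
    support: frozenset[str]
    support_count: int
    resolved_genotype: GenotypeCall

    def to_record(self, sample_name: str = "SAMPLE") -> SVRecord:
        """Consensus SVRecord: representative + support annotations."""
        rec = self.representative.copy()
        rec.info = dict(rec.info)
        rec.info["SUPP"] = str(self.support_count)
        rec.info["SUPP_CALLERS"] = ",".join(sorted(self.support))
        rec.samples = {sample_name: self.resolved_genotype}
        return rec


def _size_ratio_ok(a: SVRecord, b: SVRecord, max_ratio: float) -> bool:
    sa, sb = a.size, b.size
    if sa is None or sb is None:
        return True
    lo, hi = min(sa, sb), max(sa, sb)
    if lo == 0:
        return hi == 0
    return hi / lo <= max_ratio


def pairwise_match(a: SVRecord, b: SVRecord, params: MergeParams) -> bool:
    """Do two same-type calls describe the same event under *params*?"""
    if a.svtype is not b.svtype:
        raise ValueError(f"type mismatch: {a.svtype} vs {b.svtype}")
    if a.svtype in (SVType.TRA, SVType.BND):
        (ac1, ap1), (ac2, ap2) = a.breakpoints()
        (bc1, bp1), (bc2, bp2) = b.breakpoints()
        if (ac1, ac2) != (bc1, bc2):
            return False
        if abs(ap1 - bp1) > params.tra_distance or abs(ap2 - bp2) > params.tra_distance:
            return False
        if params.require_strand_match_tra and not strands_consistent(a.strands, b.strands):
            return False
        return True
    if a.chrom != b.chrom:
        return False
    if abs(a.pos - b.pos) > params.max_distance:
        return False
    if a.svtype is SVType.INS:
        return _size_ratio_ok(a, b, params.max_size_ratio)
    a_end = a.end if a.end is not None else a.pos
    b_end = b.end if b.end is not None else b.pos
    if abs(a_end - b_end) > params.max_distance:
        return False
    if not _size_ratio_ok(a, b, params.max_size_ratio):
        return False
    return jaccard(a, b) >= params.min_jaccard


def _bucket_key(rec: SVRecord):
    if rec.svtype in (SVType.TRA, SVType.BND):
        (c1, _), (c2, _) = rec.breakpoints()
        return (rec.svtype, c1, c2)
    return (rec.svtype, rec.chrom, "")


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _caller_rank(caller: str, order: Sequence[str]) -> int:
    try:
        return order.index(caller)
    except ValueError:
        return len(order)


def resolve_genotype(
    members: Sequence[SVRecord], caller_order: Sequence[str] = ()
) -> GenotypeCall:
    """Hierarchical genotype resolution: majority -> highest variant AD ->
    caller input order."""
    if not members:
        raise ValueError("resolve_genotype needs at least one member")

    def norm_gt(rec: SVRecord) -> str:
        call = rec.first_genotype()
        gt = call.gt if call is not None else "./."
        alleles = sorted(gt.replace("|", "/").split("/"))
        return "/".join(alleles)

    counts: dict[str, int] = {}
    for rec in members:
        counts[norm_gt(rec)] = counts.get(norm_gt(rec), 0) + 1
    top = max(counts.values())
    tied = {gt for gt, c in counts.items() if c == top}
    pool = [rec for rec in members if norm_gt(rec) in tied]
    if len(tied) > 1:
        with_ad = [rec for rec in pool if rec.variant_reads is not None]
        if with_ad:
            best_ad = max(rec.variant_reads for rec in with_ad)
            pool = [rec for rec in with_ad if rec.variant_reads == best_ad]
        if len(pool) > 1:
            pool.sort(key=lambda rec: (_caller_rank(rec.source_caller, caller_order)))
    winner = pool[0]
    call = winner.first_genotype()
    return call if call is not None else GenotypeCall()


def _pick_representative(
    members: Sequence[SVRecord], caller_order: Sequence[str]
) -> SVRecord:
    # highest QUAL, then highest variant AD, then caller input order, then id
    def key(rec: SVRecord):
        qual = rec.qual if rec.qual is not None else float("-inf")
        ad = rec.variant_reads if rec.variant_reads is not None else -1
        return (-qual, -ad, _caller_rank(rec.source_caller, caller_order), rec.record_id)

    return min(members, key=key)


def cluster(
    records: Sequence[SVRecord],
    params: Optional[MergeParams] = None,
    caller_order: Optional[Sequence[str]] = None,
) -> list[MergedRecord]:
    """Partition records into consensus events (connected components of the
    pairwise-match graph within each type/chromosome bucket)."""
    params = params or MergeParams()
    if caller_order is None:
        caller_order = []
        for rec in records:
            if rec.source_caller not in caller_order:
                caller_order.append(rec.source_caller)

    buckets: dict[tuple, list[int]] = {}
    for i, rec in enumerate(records):
        buckets.setdefault(_bucket_key(rec), []).append(i)

    uf = _UnionFind(len(records))
    for key, idxs in buckets.items():
        window = params.tra_distance if key[0] in (SVType.TRA, SVType.BND) else params.max_distance
        # prune on the canonical first breakpoint (matters for TRA records
        # whose stored chrom sorts after chrom2)
        bp1 = {i: records[i].breakpoints()[0][1] for i in idxs}
        idxs = sorted(idxs, key=lambda i: (bp1[i], records[i].record_id))
        for a_rank, i in enumerate(idxs):
            for j in idxs[a_rank + 1:]:
                if bp1[j] - bp1[i] > window:
                    break
                if pairwise_match(records[i], records[j], params):
                    uf.union(i, j)

    components: dict[int, list[int]] = {}
    for i in range(len(records)):
        components.setdefault(uf.find(i), []).append(i)

    merged: list[MergedRecord] = []
    for idxs in components.values():
        members = sorted(
            (records[i] for i in idxs),
            key=lambda r: (r.chrom, r.pos, r.source_caller, r.record_id),
        )
        support = frozenset(r.source_caller for r in members)
        merged.append(
            MergedRecord(
                representative=_pick_representative(members, caller_order),
                members=members,
                support=support,
                support_count=len(support),
                resolved_genotype=resolve_genotype(members, caller_order),
            )
        )
    merged.sort(key=lambda m: (m.representative.chrom, m.representative.pos,
                               m.representative.record_id))
    return merged


@dataclass
class FilterReport:
    input_count: int = 0
    passed: int = 0
    dropped_below_threshold: int = 0
    dropped_missing_attribute: int = 0
    dropped_missing_by: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "passed": self.passed,
            "dropped_below_threshold": self.dropped_below_threshold,
            "dropped_missing_attribute": self.dropped_missing_attribute,
            "dropped_missing_by": dict(self.dropped_missing_by),
        }


def quality_filter(
    merged: Iterable[MergedRecord],
    min_qual: Optional[float] = None,
    min_support_reads: Optional[int] = None,
    min_dp: Optional[int] = None,
    min_gq: Optional[int] = None,
) -> tuple[list[MergedRecord], FilterReport]:
    """Post-merge quality screen on each consensus record's representative.

    A record whose representative is missing an attribute that has a
    threshold set is dropped and counted separately.
    """
    report = FilterReport()
    kept: list[MergedRecord] = []
    for m in merged:
        report.input_count += 1
        rep = m.representative
        call = rep.first_genotype() or GenotypeCall()
        checks = [
            ("QUAL", min_qual, rep.qual),
            ("AD", min_support_reads, call.variant_reads),
            ("DP", min_dp, call.dp),
            ("GQ", min_gq, call.gq),
        ]
        verdict = "pass"
        for name, threshold, value in checks:
            if threshold is None:
                continue
            if value is None:
                verdict = f"missing:{name}"
                break
            if value < threshold:
                verdict = "below"
                break
        if verdict == "pass":
            kept.append(m)
            report.passed += 1
        elif verdict == "below":
            report.dropped_below_threshold += 1
        else:
            report.dropped_missing_attribute += 1
            attr = verdict.split(":", 1)[1]
            report.dropped_missing_by[attr] = report.dropped_missing_by.get(attr, 0) + 1
    return kept, report
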