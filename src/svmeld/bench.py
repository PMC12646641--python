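"""Benchmark callsets against truth sets; truth-free trio evaluation.

Truth matching is one-to-one and greedy by ascending breakpoint distance: a
call matches a truth record when types agree (unless disabled), breakpoint
distances are within ``position_threshold`` (translocations use the more
permissive ``tra_position_threshold`` on both breakpoints), and the size
ratio min/max reaches ``min_size_ratio`` (waived for TRA, which has no
length). Precision, recall and F1 are reported overall and per SV type.

The Mendelian violation rate (MVR) is a truth-free false-positive proxy for
trios: the fraction of the child's variants absent from both parents after a
joint three-way merge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from intervaltree import IntervalTree

from .merge import MergeParams, cluster
from .records import SVRecord, SVType
from .vcf_io import write_vcf

__all__ = [
    "BenchParams",
    "BenchmarkReport",
    "MVRResult",
    "match_truth",
    "write_bench_outputs",
    "mendelian_violation_rate",
]

REPORT_SCHEMA_VERSION = "1.0"


@dataclass
class BenchParams:
    position_threshold: int = 500
    min_size_ratio: float = 0.7
    require_type_match: bool = True
    tra_position_threshold: int = 5000

    def __post_init__(self) -> None:
        if self.position_threshold <= 0:
            raise ValueError("position_threshold must be > 0")
        if not (0 < self.min_size_ratio <= 1):
            raise ValueError("min_size_ratio must be in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "position_threshold": self.position_threshold,
            "min_size_ratio": self.min_size_ratio,
            "require_type_match": self.require_type_match,
            "tra_position_threshold": self.tra_position_threshold,
        }


def _prf(tp: int, fp: int, fn: int) -> dict:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"tp": tp, "fp": fp, "fn": fn,
            "precision": precision, "recall": recall, "f1": f1}


@dataclass
class BenchmarkReport:
    tp: list[tuple[SVRecord, SVRecord]]  # (call, truth)
    fp: list[SVRecord]
    fn: list[SVRecord]
    metrics: dict
    params: BenchParams
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "params": self.params.to_dict(),
            "counts": {"calls": len(self.tp) + len(self.fp),
                       "truth": len(self.tp) + len(self.fn)},
            "overall": self.metrics["overall"],
            "by_type": self.metrics["by_type"],
            "warnings": list(self.warnings),
        }


def _match_distance(call: SVRecord, truth: SVRecord, params: BenchParams) -> Optional[int]:
    """Breakpoint distance if the pair is matchable under params, else None."""
    if params.require_type_match and call.svtype is not truth.svtype:
        return None
    two_sided = call.svtype in (SVType.TRA, SVType.BND) or truth.svtype in (
        SVType.TRA, SVType.BND)
    if two_sided:
        (cc1, cp1), (cc2, cp2) = call.breakpoints()
        (tc1, tp1), (tc2, tp2) = truth.breakpoints()
        if (cc1, cc2) != (tc1, tc2):
            return None
        d = max(abs(cp1 - tp1), abs(cp2 - tp2))
        if d > params.tra_position_threshold:
            return None
        return d
    if call.chrom != truth.chrom:
        return None
    c_end = call.end if call.end is not None else call.pos
    t_end = truth.end if truth.end is not None else truth.pos
    d = max(abs(call.pos - truth.pos), abs(c_end - t_end))
    if d > params.position_threshold:
        return None
    cs, ts = call.size, truth.size
    if cs is not None and ts is not None:
        lo, hi = min(cs, ts), max(cs, ts)
        if hi > 0 and lo / hi < params.min_size_ratio:
            return None
    return d


def match_truth(
    calls: Sequence[SVRecord],
    truth: Sequence[SVRecord],
    params: Optional[BenchParams] = None,
) -> BenchmarkReport:
    """Score *calls* against *truth*; each truth record is consumed at most once."""
    params = params or BenchParams()
    warnings: list[str] = []
    if not truth:
        warnings.append("empty truth set: recall undefined, reported as 0")

    candidates: list[tuple[int, int, int]] = []  # (distance, truth_idx, call_idx)
    for ci, call in enumerate(calls):
        for ti, t in enumerate(truth):
            d = _match_distance(call, t, params)
            if d is not None:
                candidates.append((d, ti, ci))
    candidates.sort()
    call_used = [False] * len(calls)
    truth_used = [False] * len(truth)
    tp: list[tuple[SVRecord, SVRecord]] = []
    for d, ti, ci in candidates:
        if call_used[ci] or truth_used[ti]:
            continue
        call_used[ci] = truth_used[ti] = True
        tp.append((calls[ci], truth[ti]))
    fp = [c for i, c in enumerate(calls) if not call_used[i]]
    fn = [t for i, t in enumerate(truth) if not truth_used[i]]

    types = sorted({r.svtype.value for r in calls} | {r.svtype.value for r in truth})
    by_type = {}
    for t in types:
        tp_t = sum(1 for c, _ in tp if c.svtype.value == t)
        fp_t = sum(1 for c in fp if c.svtype.value == t)
        fn_t = sum(1 for r in fn if r.svtype.value == t)
        by_type[t] = _prf(tp_t, fp_t, fn_t)
    metrics = {"overall": _prf(len(tp), len(fp), len(fn)), "by_type": by_type}
    return BenchmarkReport(tp=tp, fp=fp, fn=fn, metrics=metrics,
                           params=params, warnings=warnings)


def write_bench_outputs(report: BenchmarkReport, prefix: str | Path) -> dict[str, Path]:
    """Write tp/fp/fn VCFs plus a JSON statistics file under *prefix*."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "tp": prefix.with_suffix(".tp.vcf"),
        "fp": prefix.with_suffix(".fp.vcf"),
        "fn": prefix.with_suffix(".fn.vcf"),
        "stats": prefix.with_suffix(".stats.json"),
    }
    write_vcf([c for c, _ in report.tp], paths["tp"])
    write_vcf(report.fp, paths["fp"])
    write_vcf(report.fn, paths["fn"])
    with open(paths["stats"], "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


# ---------------------------------------------------------------------------
# trio Mendelian violation rate

CHILD, FATHER, MOTHER = "child", "father", "mother"


@dataclass
class MVRResult:
    mvr: float
    violations: int
    denominator: int
    by_type: dict[str, dict]
    excluded_short: int = 0
    excluded_masked: int = 0
    excluded_filtered: int = 0

    def to_dict(self) -> dict:
        return {
            "mvr": self.mvr,
            "violations": self.violations,
            "denominator": self.denominator,
            "by_type": dict(self.by_type),
            "excluded_short": self.excluded_short,
            "excluded_masked": self.excluded_masked,
            "excluded_filtered": self.excluded_filtered,
        }


def _load_mask(exclude_bed) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    if exclude_bed is None:
        return trees
    if isinstance(exclude_bed, (str, Path)):
        rows = []
        with open(exclude_bed) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split("\t")[:3]
                rows.append((chrom, int(start), int(end)))
    else:
        rows = list(exclude_bed)
    for chrom, start, end in rows:
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def _masked(rec: SVRecord, trees: dict[str, IntervalTree]) -> bool:
    if not trees:
        return False
    lo, hi = rec.interval()
    tree = trees.get(rec.chrom)
    if tree is not None and tree.overlap(lo - 1, hi - 1):  # BED is 0-based
        return True
    if rec.chrom2 is not None and rec.pos2 is not None:
        tree2 = trees.get(rec.chrom2)
        if tree2 is not None and tree2.overlap(rec.pos2 - 1, rec.pos2):
            return True
    return False


def mendelian_violation_rate(
    child: Sequence[SVRecord],
    father: Sequence[SVRecord],
    mother: Sequence[SVRecord],
    merge_params: Optional[MergeParams] = None,
    min_svlen: int = 30,
    exclude_bed=None,
    filter_pass_only: bool = False,
) -> MVRResult:
    """Trio MVR: fraction of the child's merged variants with neither parent
    in the support set.

    The three callsets are merged jointly (child/father/mother as three
    support slots); child variants shorter than *min_svlen* are excluded
    from the denominator (TRA and BND are exempt from the length filter).
    An optional BED mask and PASS-filter screen exclude child variants in
    untrusted regions or with caller-assigned filters.
    """
    if not child:
        raise ValueError("empty child callset: MVR is undefined")
    merge_params = merge_params or MergeParams()
    mask = _load_mask(exclude_bed)

    tagged: list[SVRecord] = []
    for role, recs in ((CHILD, child), (FATHER, father), (MOTHER, mother)):
        for rec in recs:
            tagged.append(rec.copy(source_caller=role))
    merged = cluster(tagged, merge_params, caller_order=[CHILD, FATHER, MOTHER])

    denominator = violations = 0
    excluded_short = excluded_masked = excluded_filtered = 0
    per_type: dict[str, list[int]] = {}
    for m in merged:
        if CHILD not in m.support:
            continue
        child_member = next(r for r in m.members if r.source_caller == CHILD)
        if child_member.svtype not in (SVType.TRA, SVType.BND):
            size = child_member.size
            if size is not None and size < min_svlen:
                excluded_short += 1
                continue
        if _masked(child_member, mask):
            excluded_masked += 1
            continue
        if filter_pass_only and child_member.filter not in ("PASS", "."):
            excluded_filtered += 1
            continue
        denominator += 1
        violated = FATHER not in m.support and MOTHER not in m.support
        violations += violated
        bucket = per_type.setdefault(child_member.svtype.value, [0, 0])
        bucket[0] += violated
        bucket[1] += 1

    if denominator == 0:
        raise ValueError("no child variants left after filtering: MVR is undefined")
    by_type = {
        t: {"violations": v, "total": n, "mvr": v / n}
        for t, (v, n) in sorted(per_type.items())
    }
    return MVRResult(
        mvr=violations / denominator,
        violations=violations,
        denominator=denominator,
        by_type=by_type,
        excluded_short=excluded_short,
        excluded_masked=excluded_masked,
        excluded_filtered=excluded_filtered,
    )
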