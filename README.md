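# svmeld

Standardize ambiguous breakend annotations, merge structural-variant (SV)
callsets from multiple callers or samples under flexible set operations, and
benchmark callsets against truth sets — including a truth-free trio
Mendelian-violation statistic.

## Who this is for

SV callers disagree not only about which variants exist but about how to
*write* them: many short-read callers (and some long-read ones) report a
large share of their calls as breakends (`BND`) — bare novel adjacencies in
VCF bracket notation — instead of canonical deletions, duplications,
inversions or translocations. Downstream merging tools often drop or
misclassify those records. `svmeld` is for anyone integrating multi-caller
or multi-sample SV callsets who needs (a) BND records resolved into
canonical types before merging, (b) set operations richer than union and
intersection, and (c) reproducible precision/recall/F1 benchmarking.

## What it does

**BND correction.** Each breakend ALT matches one of four bracket patterns
(`t[p[`, `t]p]`, `]p]t`, `[p[t`) encoding which side of each breakpoint is
joined and in what strand sense. Mates are paired first by `MATEID`, then
positionally within a configurable tolerance (default 3 bp). For a
same-chromosome pair with leftmost half L and rightmost half R:

| L            | R            | call            |
|--------------|--------------|-----------------|
| `t[p[` → R   | `]p]t` → L   | DEL             |
| `]p]t` → R   | `t[p[` → L   | tandem DUP      |
| `t]p]` both, or `[p[t` both | | INV             |
| anything else, or span < 50 bp | | retained as BND |

Cross-chromosome pairs become TRA records subtyped *balanced* (two
reciprocal junctions), *unbalanced* (a lone junction), or *merging*
(duplicate representations of one junction, collapsed). BNDs are never
converted to INS — insertion calling needs sequence content that breakpoint
coordinates cannot supply — and anything ambiguous is retained, with every
decision recorded in an audit table.

**Merging.** Calls of the same type match when start/end distances are
within `max_distance` (default 50 bp), the size ratio max/min is ≤ 1.3, and
the interval Jaccard index (intersection/union) is ≥ 0.7; point-like
insertions skip the Jaccard test, and translocations use a more permissive
500 bp breakpoint distance with strand consistency. Matching records are
clustered by transitive closure; each cluster becomes one consensus event
with a supporting-caller set. Selections over those support sets accept
full boolean expressions — `(manta AND svaba) NOT (lumpy OR delly)`,
`min_support(2)`, `max_support(2)` — with union ≡ `min_support(1)` and
intersection ≡ `min_support(N)`. Conflicting genotypes resolve by majority
vote, then highest variant-supporting read count (AD), then caller input
order.

**Benchmarking.** One-to-one greedy matching against a truth set (500 bp
position threshold, minimum size ratio 0.7, type-aware; 5000 bp for
translocations) gives TP/FP/FN partitions and precision/recall/F1 overall
and per type. For trios, the Mendelian violation rate — the fraction of the
child's variants absent from both parents after a joint three-way merge —
serves as a truth-free false-positive proxy (variants under 30 bp excluded,
TRA/BND exempt).

**Fixtures.** A call-level generator plants exact SV events on a
coordinates-only genome model and emits caller-style VCFs with configurable
BND encoding, breakpoint jitter, drop-out and spurious calls, so every
claim above is testable without external data.

## Worked example

Three synthetic callers observe the same 145 planted events with breakpoint
jitter, 10% drop-out, a mix of canonical and BND encodings, and five
spurious calls each; correction and a min-support-2 consensus recover them:

```python
import json
from svmeld import *
from svmeld.setops import MinSupport

truth = plant_events({"DEL": 40, "INS": 30, "INV": 30, "DUP": 30, "TRA": 15}, seed=7)
profiles = [
    CallerProfile("manta", bnd_fraction=0.6, jitter_sd=5.0, fn_rate=0.1, fp_count=5),
    CallerProfile("delly", bnd_fraction=0.2, jitter_sd=8.0, fn_rate=0.1, fp_count=5),
    CallerProfile("lumpy", bnd_fraction=0.4, jitter_sd=3.0, fn_rate=0.1, fp_count=5),
]
corrected = []
for i, p in enumerate(profiles):
    callset = emit_caller_records(truth, p, seed=10 + i)
    result = correct(callset.records)
    print(f"{p.name}: {len(callset.records)} records in, "
          f"{len(result.corrected)} canonical, {len(result.retained_bnd)} BND retained")
    corrected.extend(result.all_records)

merged = cluster(corrected, MergeParams(), caller_order=[p.name for p in profiles])
consensus = apply_set_operation(merged, MinSupport(2))
print(f"merged events: {len(merged)}, supported by >=2 callers: {len(consensus)}")

report = match_truth([m.to_record() for m in consensus], truth.events)
print(json.dumps(report.metrics["overall"], indent=2))
```

Output:

```text
manta: 199 records in, 132 canonical, 0 BND retained
delly: 157 records in, 134 canonical, 0 BND retained
lumpy: 178 records in, 133 canonical, 0 BND retained
merged events: 160, supported by >=2 callers: 140
{
  "tp": 140,
  "fp": 0,
  "fn": 5,
  "precision": 1.0,
  "recall": 0.9655172413793104,
  "f1": 0.9824561403508771
}
```

`manta` emits 199 records because 60% of its non-insertion events are
written as breakend *pairs* (two VCF lines per event); correction collapses
them back to 132 canonical calls. The consensus keeps all 140 events seen
by at least two callers — the 15 per-caller spurious calls never reach
support 2, so precision is 1.0 — and misses 5 events dropped by two callers
at once.

The same pipeline is available from the shell:

```bash
svmeld synth --seed 7 --out fixtures/
svmeld correct --input fixtures/caller1.vcf --output caller1.svcf
svmeld merge --input fixtures/caller1.vcf --input fixtures/caller2.vcf \
             --mode min-support --support-count 2 --output merged.svcf
svmeld benchmark --calls merged.svcf --truth fixtures/truth.vcf --out bench
svmeld trio-mvr --child c.vcf --father f.vcf --mother m.vcf
svmeld svcf2vcf --input merged.svcf --output merged.vcf
svmeld stat --input merged.svcf --json
```

Intermediate results use SVCF, a versioned tab-separated serialization of
the normalized record model that keeps caller provenance and support
annotations; `svcf2vcf` converts back to standard VCF.

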