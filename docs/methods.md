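# Methods

This note documents the models and procedures implemented in `svmeld`, the
parameter defaults and why they were chosen, what the synthetic fixture
generator does and does not emulate, and the numerical/design decisions a
maintainer would want to know.

## Record model and coordinates

All operations run on a normalized record (`SVRecord`): one SV call with a
canonical type (`DEL`, `INS`, `INV`, `DUP`, `TRA`) or an unresolved `BND`.
Coordinates are 1-based and fully closed, exactly as VCF prints them;
interval arithmetic converts to half-open `[pos, end)` only inside overlap
computations, so an interval's length is `end − pos`. This keeps the I/O
boundary translation-free and confines off-by-one risk to one function.

Missing `SVLEN` for DEL/DUP/INV is derived as `END − POS` (negative for
DEL); missing `END` is derived as `POS + |SVLEN|`. A record missing both is
rejected into a per-file rejects report rather than aborting the parse.
Multi-allelic lines are split into one record per ALT. Per-caller adapters
absorb dialect quirks: DELLY's `CHR2`+`END` second breakpoint and `CT`
connection-type strands, LUMPY's `STRANDS` tag, Sniffles-style `DR`/`DV`
depth pairs and `SUPPORT`/`RE` read counts used as an AD fallback when the
`AD` FORMAT field is absent. Unknown callers get a generic adapter with the
same fallback chain. VCF reading and writing go through `pysam`
(htslib); QUAL is rounded to three decimals on read because htslib stores
it as a 32-bit float.

SVCF, the tabular intermediate format, is a versioned, tab-separated,
lossless serialization of `SVRecord` (fixed columns, `GT:AD:DP:GQ` sample
columns, residual INFO as `key=value` pairs). Its reader rejects
major-version mismatches explicitly. The column schema is this package's
own; it is documented in `svcf.py`.

## BND correction

Breakend ALTs are parsed into one of the four bracket orientations. Mate
pairing is hierarchical:

1. `MATEID` cross-references (one-directional suffices).
2. Greedy positional pairing: two halves are matchable at tolerance *t*
   when both cross-distances (|a.mate_pos − b.pos| and |b.mate_pos − a.pos|)
   are ≤ *t* and the chromosomes cross-match. Candidates are taken smallest
   summed cross-distance first, ties by input order. Default tolerance 3 bp.

The *matchability relation* is monotone in the tolerance; the greedy
matching itself is not guaranteed monotone (a newly admissible
smaller-mismatch pair can re-partner halves), which is why the test suite
asserts monotonicity of the relation plus non-vanishing of the matching
rather than strict subset inclusion of pairings.

Same-chromosome pairs are classified by the decision table in the README:
the only junction topologies consistent with a deletion (forward junction
skipping the span), a tandem duplication (junction running 3′→5′ back
across the span), or an inversion (same-side brackets on both halves).
Everything else — including pairs spanning < 50 bp, below the conventional
SV size definition — is retained as BND. Cross-chromosome pairings
collapse to one TRA each (stored with the lexicographically smaller contig
first). Two pairings over the same chromosome pair whose breakpoints agree
within tolerance are either *merging* (identical per-chromosome
orientations: duplicate evidence for one junction, collapsed to one
record) or *balanced* (complementary orientations — at each chromosome one
half keeps the 5′ side and the other the 3′ side — i.e. a reciprocal
exchange; both partners stay as separate annotated records). Lone pairings
and unpaired halves become *unbalanced* TRAs, the latter flagged `no_mate`
in the audit. BNDs are never converted to INS.

The genotype of a collapsed pair is taken from the half with the higher
variant-supporting read count, falling back to the first half. Every input
record appears exactly once in the audit (`pass_through`, `converted`,
`collapsed`, or `retained` with a rule name), which is what makes the
conservation and idempotence properties checkable.

## Merging

Matching thresholds (`MergeParams`): breakpoint distance 50 bp on both
start and end (the strict end of the conventional 50–150 bp range; exposed
as a single knob), size ratio max/min ≤ 1.3, interval Jaccard ≥ 0.7.
Insertions are point-like, so the Jaccard test is waived for them and they
match on position distance and SVLEN ratio alone. Translocations match on
both breakpoints within 500 bp on the same (unordered) chromosome pair,
requiring consistent strand pairs; records with unknown strands are
treated as consistent with anything, since several dialects do not encode
strands at all.

Clustering is single-linkage: connected components of the pairwise-match
graph within each (type, chromosome-pair) bucket, computed by union-find
with a sorted sliding window over the canonical first breakpoint (valid
because no match can span more than the distance threshold). Components
were chosen over cliques to match prevailing merge-tool behaviour and
because they admit a trivially correct brute-force oracle (transitive
closure), against which the implementation is tested on random instances.

Per consensus event: the representative is the member with highest QUAL,
ties by highest variant AD, then caller input order, then record id (the
last tie-break makes representatives stable under input shuffling);
genotypes resolve by majority vote over normalized GT tokens (phase
stripped, alleles sorted), then highest variant AD among the tied
genotypes, then caller input order. Support-set selection accepts a
boolean expression grammar with precedence NOT > AND > OR; `NOT` between
two terms is binary set difference (`a NOT b ≡ a AND NOT b`), matching the
bracketed difference idiom used in multi-caller workflows, and unary NOT
is also accepted. Quality filtering (QUAL, variant-supporting reads, DP,
GQ) applies to the representative; a record missing an attribute that has
a threshold set is dropped and counted separately in the filter report.

## Benchmarking and trio MVR

Truth matching is greedy nearest-first and one-to-one: candidate pairs
must agree in type (unless disabled), lie within 500 bp on both start and
end (5000 bp on both breakpoints for TRA/BND), and reach size ratio
min/max ≥ 0.7 (waived for TRA, which has no length; waived when either
size is undefined). Candidates are consumed in order of ascending
breakpoint distance (the maximum of the per-breakpoint deltas), ties by
truth input order. Per-type metrics are computed independently from that
type's own TP/FP/FN; with type matching required, cross-type matches
cannot occur. An empty truth set yields recall 0 with an explicit warning
rather than an error.

The Mendelian violation rate merges child, father and mother as three
support slots with the standard merge parameters, then computes the
fraction of child-supported consensus events with neither parent in the
support set. Child variants shorter than 30 bp are excluded from the
denominator (TRA and BND exempt, having no meaningful length). An optional
BED exclusion mask and a PASS-filter screen (both off by default) stand in
for repeat/mappability filtering, whose source annotation is necessarily
external to this package. An empty child set, or a child set emptied by
filtering, is an error: the statistic is undefined there.

## Synthetic fixture generator

The generator works at the *call* level, not the read level: it plants
exact, non-overlapping events on a coordinates-only genome model (three
contigs of 6–10 Mb by default) and then distorts them per caller profile.
Defaults: heterozygous fraction 0.7 (a 30:70 hom:het mix), event sizes
uniform on 100–10 000 bp — the mid-size range where call-level merging
behaviour is actually exercised; the generator refuses sizes below the
50 bp SV definition. Caller profiles control the BND-encoding fraction
(all four bracket orientations are produced, DEL/DUP/INV/TRA each with
their correct junction topology), MATEID presence (default 50%, so
positional pairing is exercised), Gaussian breakpoint jitter (applied
independently to both breakpoints, truncated to contig bounds), drop-out,
and spurious calls placed ≥ 10 kb from any same-type truth event. Depths,
genotype qualities and QUALs are drawn from simple uniform ranges; QUAL is
rounded to one decimal so files round-trip bit-exactly through htslib.

What this does *not* emulate: read-level artefacts (alignment noise,
coverage dips, repeat-driven mis-calls), caller-specific systematic biases,
overlapping/nested events, and sub-100 bp events whose breakpoint
uncertainty in real data is dominated by alignment, not by Gaussian
jitter. Passing tests therefore demonstrate the correctness of the
*algorithms* (classification, clustering, arithmetic) under controlled
noise — not field performance on real sequencing data, where upstream
caller error dominates.

## Problem sizes and verification

The test suite and the acceptance script use desk-scale problem sizes
chosen as this package's own verification conditions: 500 events per type
for noiseless BND recovery, 100 random instances of up to 200 records for
the clustering oracle, 675 planted events across three noisy callers for
the end-to-end consensus property (recall ≥ 0.95 at precision ≥ 0.99 with
default parameters), and a ~500-variant constructed trio for the MVR
(father/mother/both carriers at 45/45/10%, 2% parental miss rate, ~2% de
novo events, yielding an MVR in the low single-digit percent range, the
scale reported for well-behaved trio callsets). The whole suite runs in a
few seconds on one CPU.

## Known limitations

- Same-chromosome classification covers the four canonical junction
  topologies; rarer sub-cases (e.g. inverted duplications) are retained as
  BND rather than guessed.
- Balanced-translocation detection pairs pairings greedily; three or more
  mutually reciprocal junctions at one locus are resolved in input order.
- Merging is sequence-unaware: no alt-allele alignment, no breakpoint
  refinement, no re-genotyping from reads.
- The merge is designed for tens of callers/samples, not for
  thousands-of-samples population sharding.
- `NOT` as set difference binds looser than AND and tighter than OR;
  expressions mixing unary and binary NOT should use parentheses for
  clarity.
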