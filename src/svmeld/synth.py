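"""Caller-style synthetic fixtures with planted ground truth.

The generator operates at the call level: it plants exact SV events on a
coordinates-only genome model, then emits per-"caller" callsets that emulate
observed caller behaviours — BND-encoded events in all four bracket
orientations (with or without MATEID), positional jitter between callers,
dropped calls (false negatives) and spurious calls (false positives placed
well away from any planted event). Genotypes follow the configured
heterozygous fraction (default 0.7, i.e. a 30:70 hom:het ratio).

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .records import GenotypeCall, SVRecord, SVType, TYPE_STRANDS
from .vcf_io import write_vcf

__all__ = [
    "DEFAULT_GENOME",
    "TruthSet",
    "CallerProfile",
    "EmittedCallset",
    "plant_events",
    "emit_caller_records",
    "emit_caller_vcf",
]

DEFAULT_GENOME: dict[str, int] = {
    "chr1": 10_000_000,
    "chr2": 8_000_000,
    "chr3": 6_000_000,
}

#: minimum separation between planted events on a contig (bp)
MIN_GAP = 2_000
#: minimum distance of a false-positive call from any same-type truth event
FP_CLEARANCE = 10_000


@dataclass
class TruthSet:
    events: list[SVRecord]
    seed: int
    genome: dict[str, int]

    def by_id(self) -> dict[str, SVRecord]:
        return {e.record_id: e for e in self.events}


@dataclass
class CallerProfile:
    """How one synthetic caller distorts the truth.

    bnd_fraction: probability a non-INS event is emitted as a breakend pair.
    jitter_sd: SD (bp) of the Gaussian shift applied to each breakpoint.
    fn_rate: probability an event is dropped entirely.
    fp_count: number of spurious events added.
    mateid_fraction: probability a breakend pair carries MATEID tags
        (otherwise mates must be recovered positionally).
    dialect: caller identifier used for adapter lookup and provenance.
    """

    name: str
    bnd_fraction: float = 0.0
    jitter_sd: float = 0.0
    fn_rate: float = 0.0
    fp_count: int = 0
    mateid_fraction: float = 0.5
    dialect: str = "generic"
    qual_range: tuple[float, float] = (30.0, 60.0)

    def __post_init__(self) -> None:
        for attr in ("bnd_fraction", "fn_rate", "mateid_fraction"):
            v = getattr(self, attr)
            if not 0 <= v <= 1:
                raise ValueError(f"{attr} must be in [0, 1], got {v}")


@dataclass
class EmittedCallset:
    records: list[SVRecord]
    #: emitted record id -> truth id ("." for false positives)
    mapping: list[tuple[str, str]] = field(default_factory=list)


def _place(
    rng: np.random.Generator,
    occupied: dict[str, list[tuple[int, int]]],
    genome: dict[str, int],
    width: int,
    contig: Optional[str] = None,
    max_tries: int = 200,
) -> tuple[str, int]:
    contigs = list(genome)
    for _ in range(max_tries):
        c = contig or contigs[rng.integers(len(contigs))]
        limit = genome[c] - width - MIN_GAP
        if limit <= MIN_GAP:
            continue
        pos = int(rng.integers(MIN_GAP, limit))
        if all(pos + width + MIN_GAP <= s or pos >= e + MIN_GAP
               for s, e in occupied.get(c, [])):
            occupied.setdefault(c, []).append((pos, pos + width))
            return c, pos
    raise ValueError(
        f"infeasible packing: cannot place a {width} bp event on "
        f"{contig or 'any contig'}"
    )


def _genotype(rng: np.random.Generator, het_fraction: float) -> str:
    return "0/1" if rng.random() < het_fraction else "1/1"


def plant_events(
    n_per_type: dict[str, int],
    size_range: tuple[int, int] = (100, 10_000),
    het_fraction: float = 0.7,
    seed: int = 0,
    genome: Optional[dict[str, int]] = None,
) -> TruthSet:
    """Plant exact SV events (DEL/INS/INV/DUP/TRA) on the genome model.

    Events of all types are placed without mutual overlap; genotypes are
    heterozygous with probability *het_fraction*. Deterministic per seed.
    """
    genome = dict(genome or DEFAULT_GENOME)
    if size_range[0] < 50:
        raise ValueError("size_range minimum must be >= 50 bp (SV definition)")
    rng = np.random.default_rng(seed)
    occupied: dict[str, list[tuple[int, int]]] = {}
    events: list[SVRecord] = []
    counter = 0
    for type_name in ("DEL", "INS", "INV", "DUP", "TRA"):
        n = int(n_per_type.get(type_name, 0))
        if n < 0:
            raise ValueError(f"negative count for {type_name}")
        svtype = SVType(type_name)
        for _ in range(n):
            counter += 1
            rid = f"truth_{type_name}_{counter}"
            size = int(rng.integers(size_range[0], size_range[1] + 1))
            gt = _genotype(rng, het_fraction)
            samples = {"truth": GenotypeCall(gt=gt)}
            if svtype is SVType.TRA:
                c1, p1 = _place(rng, occupied, genome, 1)
                c2, p2 = _place(rng, occupied, genome, 1)
                while c2 == c1:
                    c2, p2 = _place(rng, occupied, genome, 1)
                if (c1, p1) > (c2, p2):
                    (c1, p1), (c2, p2) = (c2, p2), (c1, p1)
                events.append(SVRecord(
                    record_id=rid, chrom=c1, pos=p1, svtype=svtype,
                    chrom2=c2, pos2=p2, strands="+-", alt_allele="<TRA>",
                    samples=samples, source_caller="truth",
                ))
                continue
            width = 1 if svtype is SVType.INS else size
            chrom, pos = _place(rng, occupied, genome, width)
            if svtype is SVType.INS:
                end, svlen = pos, size
            elif svtype is SVType.DEL:
                end, svlen = pos + size, -size
            else:
                end, svlen = pos + size, size
            events.append(SVRecord(
                record_id=rid, chrom=chrom, pos=pos, svtype=svtype,
                end=end, svlen=svlen,
                strands=TYPE_STRANDS.get(svtype, "++" if svtype is SVType.INV else ".."),
                alt_allele=f"<{type_name}>",
                samples=samples, source_caller="truth",
            ))
    return TruthSet(events=events, seed=seed, genome=genome)


def _jitter(rng: np.random.Generator, pos: int, sd: float, upper: int) -> int:
    if sd <= 0:
        return pos
    shifted = pos + int(round(rng.normal(0.0, sd)))
    return max(1, min(upper, shifted))


def _sample_call(rng: np.random.Generator, gt: str) -> GenotypeCall:
    dp = int(rng.integers(20, 60))
    var = dp if gt == "1/1" else max(1, dp // 2)
    return GenotypeCall(gt=gt, ad=(dp - var, var), dp=dp,
                        gq=int(rng.integers(30, 99)))


def _bnd_pair(
    event: SVRecord, rid: str, qual: float, call: GenotypeCall,
    with_mateid: bool, caller: str,
) -> list[SVRecord]:
    """Encode one canonical event as its two breakend halves."""
    c, p = event.chrom, event.pos
    if event.svtype is SVType.TRA:
        c2, p2 = event.chrom2, event.pos2
    else:
        c2, p2 = event.chrom, event.end
    if event.svtype is SVType.DUP:
        alt1, alt2 = f"]{c2}:{p2}]N", f"N[{c}:{p}["
    elif event.svtype is SVType.INV:
        alt1, alt2 = f"N]{c2}:{p2}]", f"N]{c}:{p}]"
    else:  # DEL and TRA share the forward-junction encoding
        alt1, alt2 = f"N[{c2}:{p2}[", f"]{c}:{p}]N"
    ids = (f"{rid}_1", f"{rid}_2")
    halves = []
    for (hc, hp), alt, hid, mate in (((c, p), alt1, ids[0], ids[1]),
                                     ((c2, p2), alt2, ids[1], ids[0])):
        info = {"MATEID": mate} if with_mateid else {}
        halves.append(SVRecord(
            record_id=hid, chrom=hc, pos=hp, svtype=SVType.BND,
            chrom2=c2 if (hc, hp) == (c, p) else c,
            pos2=p2 if (hc, hp) == (c, p) else p,
            alt_allele=alt, qual=qual, info=info,
            samples={"SAMPLE": call}, source_caller=caller,
        ))
    return halves


def emit_caller_records(
    truth: TruthSet,
    profile: CallerProfile,
    seed: int = 0,
) -> EmittedCallset:
    """Distort the truth set through one caller profile (in memory)."""
    rng = np.random.default_rng(seed)
    out = EmittedCallset(records=[])
    k = 0
    for event in truth.events:
        if rng.random() < profile.fn_rate:
            continue
        k += 1
        rid = f"{profile.name}_{k}"
        qual = round(float(rng.uniform(*profile.qual_range)), 1)
        gt = next(iter(event.samples.values())).gt if event.samples else "0/1"
        call = _sample_call(rng, gt)
        limit1 = truth.genome[event.chrom]
        pos = _jitter(rng, event.pos, profile.jitter_sd, limit1)
        if event.svtype is SVType.TRA:
            pos2 = _jitter(rng, event.pos2, profile.jitter_sd,
                           truth.genome[event.chrom2])
            jittered = event.copy(record_id=rid, pos=pos, pos2=pos2,
                                  qual=qual, samples={"SAMPLE": call},
                                  source_caller=profile.name)
        elif event.svtype is SVType.INS:
            jittered = event.copy(record_id=rid, pos=pos, end=pos, qual=qual,
                                  samples={"SAMPLE": call},
                                  source_caller=profile.name)
        else:
            end = _jitter(rng, event.end, profile.jitter_sd, limit1)
            if end <= pos:
                end = pos + 1
            svlen = end - pos
            jittered = event.copy(
                record_id=rid, pos=pos, end=end,
                svlen=-svlen if event.svtype is SVType.DEL else svlen,
                qual=qual, samples={"SAMPLE": call}, source_caller=profile.name,
            )
        as_bnd = (
            event.svtype is not SVType.INS
            and rng.random() < profile.bnd_fraction
        )
        if as_bnd:
            with_mateid = rng.random() < profile.mateid_fraction
            halves = _bnd_pair(jittered, rid, qual, call, with_mateid, profile.name)
            out.records.extend(halves)
            for h in halves:
                out.mapping.append((h.record_id, event.record_id))
        else:
            out.records.append(jittered)
            out.mapping.append((rid, event.record_id))

    # spurious calls, placed away from same-type truth events
    fp_types = [SVType.DEL, SVType.INS, SVType.INV, SVType.DUP]
    contigs = list(truth.genome)
    for i in range(profile.fp_count):
        svtype = fp_types[int(rng.integers(len(fp_types)))]
        for _ in range(200):
            chrom = contigs[int(rng.integers(len(contigs)))]
            size = int(rng.integers(100, 5_000))
            pos = int(rng.integers(1, truth.genome[chrom] - size - 1))
            clear = all(
                e.chrom != chrom
                or e.svtype is not svtype
                or abs(e.pos - pos) >= FP_CLEARANCE
                for e in truth.events
            )
            if clear:
                break
        rid = f"{profile.name}_fp_{i + 1}"
        call = _sample_call(rng, "0/1")
        out.records.append(SVRecord(
            record_id=rid, chrom=chrom, pos=pos, svtype=svtype,
            end=pos if svtype is SVType.INS else pos + size,
            svlen=-size if svtype is SVType.DEL else size,
            strands=TYPE_STRANDS.get(svtype, "++" if svtype is SVType.INV else ".."),
            alt_allele=f"<{svtype.value}>",
            qual=round(float(rng.uniform(*profile.qual_range)), 1),
            samples={"SAMPLE": _sample_call(rng, "0/1")},
            source_caller=profile.name,
        ))
        out.mapping.append((rid, "."))
    return out


def emit_caller_vcf(
    truth: TruthSet,
    profile: CallerProfile,
    seed: int,
    vcf_path: str | Path,
    mapping_path: Optional[str | Path] = None,
) -> EmittedCallset:
    """Emit one caller's VCF plus the emitted-id -> truth-id mapping TSV."""
    callset = emit_caller_records(truth, profile, seed)
    write_vcf(callset.records, vcf_path)
    if mapping_path is not None:
        with open(mapping_path, "w") as fh:
            fh.write("emitted_id\ttruth_id\n")
            for emitted, tid in callset.mapping:
                fh.write(f"{emitted}\t{tid}\n")
    return callset
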