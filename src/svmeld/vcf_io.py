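"""Read caller VCFs into the normalized record model and write records back.

Reading goes through :class:`pysam.VariantFile`; per-caller adapters absorb
dialect quirks (DELLY's CHR2/END second breakpoint, LUMPY's STRANDS tag,
Sniffles' DR/DV and SUPPORT naming, ...). Unknown callers get the generic
adapter. Records whose coordinates cannot be resolved are collected into a
rejects report instead of aborting the parse.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pysam

from .records import GenotypeCall, SVRecord, SVType, normalize_len_end

__all__ = [
    "ParseError",
    "RejectedRecord",
    "read_vcf",
    "write_vcf",
    "normalize_record",
]


class ParseError(ValueError):
    """Raised when a VCF header or file is unreadable."""


@dataclass
class RejectedRecord:
    record_id: str
    chrom: str
    pos: int
    reason: str


# DELLY connection-type tag -> strand pair
_CT_STRANDS = {"3to5": "+-", "5to3": "-+", "3to3": "++", "5to5": "--"}

_BND_ALT_RE = re.compile(r"^[A-Za-z.*]*[\[\]][^:\[\]]+:\d+[\[\]][A-Za-z.*]*$")


@dataclass
class CallerAdapter:
    """How to pull strands and variant-supporting reads out of one dialect."""

    name: str = "generic"
    # FORMAT tag pairs meaning (ref_reads, variant_reads), tried in order
    depth_pairs: Sequence[tuple[str, str]] = (("DR", "DV"), ("RR", "RV"))
    # INFO tags holding a bare variant-supporting read count
    support_tags: Sequence[str] = ("SUPPORT", "RE", "SU")


ADAPTERS: dict[str, CallerAdapter] = {
    "generic": CallerAdapter(),
    "delly": CallerAdapter("delly", depth_pairs=(("DR", "DV"), ("RR", "RV"))),
    "lumpy": CallerAdapter("lumpy", support_tags=("SU", "PE", "SR")),
    "sniffles": CallerAdapter("sniffles", support_tags=("SUPPORT", "RE")),
    "svim": CallerAdapter("svim", support_tags=("SUPPORT",)),
    "cutesv": CallerAdapter("cutesv", support_tags=("RE",)),
}


def _adapter(caller: str) -> CallerAdapter:
    return ADAPTERS.get(caller.lower(), ADAPTERS["generic"])


def _info_get(vrec, key):
    """INFO lookup tolerant of tags missing from the header."""
    try:
        return vrec.info.get(key)
    except (KeyError, ValueError):
        return None


def _scalar(value) -> Optional[str]:
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        return ",".join("" if v is None else str(v) for v in value)
    return str(value)


def _first_int(value) -> Optional[int]:
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        value = value[0]
    try:
        return int(value)
    except (TypeError, ValueError):
        return None


def _format_gt(sample) -> str:
    gt = sample.get("GT")
    if gt is None or all(a is None for a in gt):
        return "./."
    sep = "|" if sample.phased else "/"
    return sep.join("." if a is None else str(a) for a in gt)


def _genotype_call(vrec, sample_name: str, adapter: CallerAdapter) -> GenotypeCall:
    sample = vrec.samples[sample_name]
    ad = sample.get("AD")
    pair: Optional[tuple[int, int]] = None
    if ad is not None and len(ad) >= 2 and all(a is not None for a in ad[:2]):
        pair = (int(ad[0]), int(ad[1]))
    if pair is None:
        for ref_tag, var_tag in adapter.depth_pairs:
            r, v = sample.get(ref_tag), sample.get(var_tag)
            if r is not None and v is not None:
                pair = (_first_int(r) or 0, _first_int(v) or 0)
                break
    if pair is None:
        for tag in adapter.support_tags:
            v = _first_int(_info_get(vrec, tag))
            if v is not None:
                pair = (0, v)
                break
    dp = _first_int(sample.get("DP"))
    gq = _first_int(sample.get("GQ"))
    return GenotypeCall(gt=_format_gt(sample), ad=pair, dp=dp, gq=gq)


def _strands_from(vrec, svtype: SVType) -> str:
    raw = _scalar(_info_get(vrec, "STRANDS"))
    if raw:
        pair = raw.split(":")[0][:2]
        if pair in ("++", "+-", "-+", "--"):
            return pair
    ct = _scalar(_info_get(vrec, "CT"))
    if ct and ct in _CT_STRANDS:
        return _CT_STRANDS[ct]
    if svtype is SVType.DEL:
        return "+-"
    if svtype is SVType.DUP:
        return "-+"
    return ".."


_TYPED_INFO = {
    "SVTYPE", "END", "SVLEN", "CHR2", "POS2", "STRANDS", "CT",
    "SUPPORT", "RE", "SU", "PE", "SR", "MATEID", "EVENT", "SUBTYPE",
    "SUPP", "SUPP_CALLERS", "CALLER", "IMPRECISE", "PRECISE", "CIPOS", "CIEND",
}

# residual INFO tags we re-emit on write (anything string-representable)
_SYMBOL_TYPES = {"DEL", "INS", "INV", "DUP", "TRA", "BND", "DUP:TANDEM", "CNV"}


def _svtype_of(vrec, alt: str) -> Optional[SVType]:
    raw = _scalar(_info_get(vrec, "SVTYPE"))
    if raw is None and alt.startswith("<") and alt.endswith(">"):
        raw = alt[1:-1]
    if raw is None and _BND_ALT_RE.match(alt):
        raw = "BND"
    if raw is None:
        return None
    raw = raw.split(":")[0].upper()
    if raw == "DUP":
        return SVType.DUP
    try:
        return SVType(raw)
    except ValueError:
        return None


def _parse_bnd_mate(alt: str) -> Optional[tuple[str, int]]:
    m = re.search(r"[\[\]]([^:\[\]]+):(\d+)[\[\]]", alt)
    if m is None:
        return None
    return m.group(1), int(m.group(2))


def normalize_record(rec: SVRecord) -> SVRecord:
    """Idempotent post-read normalization (SVLEN/END completion, sign fix)."""
    rec = normalize_len_end(rec)
    if rec.svtype is SVType.DEL and rec.svlen is not None and rec.svlen > 0:
        rec.svlen = -rec.svlen
    if rec.svtype in (SVType.DUP, SVType.INV) and rec.svlen is not None and rec.svlen < 0:
        rec.svlen = -rec.svlen
    return rec


def read_vcf(
    path: str | Path,
    caller: str = "generic",
    rejects: Optional[list[RejectedRecord]] = None,
) -> list[SVRecord]:
    """Parse one caller VCF into normalized :class:`SVRecord` objects.

    Multi-allelic lines are split into one record per ALT. Records with
    unresolvable coordinates are appended to *rejects* (when given) and
    skipped; a malformed header raises :class:`ParseError`.
    """
    path = str(path)
    adapter = _adapter(caller)
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise ParseError(f"cannot parse VCF header of {path}: {exc}") from exc
    records: list[SVRecord] = []
    with vf:
        sample_names = list(vf.header.samples)
        for i, vrec in enumerate(vf):
            alts = vrec.alts or ("",)
            for j, alt in enumerate(alts):
                rid = vrec.id or f"{Path(path).stem}_{i + 1}"
                if len(alts) > 1:
                    rid = f"{rid}.{j + 1}"
                try:
                    rec = _to_record(vrec, alt, rid, path, caller, adapter, sample_names)
                except ValueError as exc:
                    if rejects is None:
                        raise
                    rejects.append(RejectedRecord(rid, vrec.chrom, vrec.pos, str(exc)))
                    continue
                records.append(rec)
    return records


def _to_record(vrec, alt, rid, path, caller, adapter, sample_names) -> SVRecord:
    svtype = _svtype_of(vrec, alt)
    if svtype is None:
        raise ValueError(f"no SVTYPE and ALT {alt!r} is not symbolic or breakend")
    end = _first_int(_info_get(vrec, "END"))
    if end is None and vrec.stop is not None and vrec.stop > vrec.pos:
        end = vrec.stop
    svlen = _first_int(_info_get(vrec, "SVLEN"))
    chrom2 = _scalar(_info_get(vrec, "CHR2"))
    pos2 = _first_int(_info_get(vrec, "POS2"))
    mate_id = _scalar(_info_get(vrec, "MATEID"))

    if svtype is SVType.BND:
        mate = _parse_bnd_mate(alt)
        if mate is None:
            raise ValueError(f"BND ALT {alt!r} does not match breakend grammar")
        chrom2, pos2 = mate
        end, svlen = None, None
    elif svtype is SVType.TRA:
        if chrom2 is None:
            raise ValueError("TRA without CHR2")
        if pos2 is None:
            pos2 = end  # DELLY convention: END carries the partner coordinate
        if pos2 is None:
            raise ValueError("TRA without POS2/END")
        end, svlen = None, None
    elif svtype is SVType.INS:
        if end is None:
            end = vrec.pos
        chrom2 = pos2 = None
    else:
        chrom2 = pos2 = None

    residual = {}
    for key in vrec.info.keys():
        if key not in _TYPED_INFO:
            val = _scalar(_info_get(vrec, key))
            residual[key] = "" if val is None else val
    if mate_id is not None:
        residual["MATEID"] = mate_id
    subtype = _scalar(_info_get(vrec, "SUBTYPE"))
    if subtype is not None:
        residual["SUBTYPE"] = subtype
    supp_callers = _scalar(_info_get(vrec, "SUPP_CALLERS"))
    if supp_callers is not None:
        residual["SUPP_CALLERS"] = supp_callers

    samples = {s: _genotype_call(vrec, s, adapter) for s in sample_names}
    rec = SVRecord(
        record_id=rid,
        chrom=vrec.chrom,
        pos=vrec.pos,
        svtype=svtype,
        end=end,
        svlen=svlen,
        chrom2=chrom2,
        pos2=pos2,
        strands=_strands_from(vrec, svtype),
        ref_allele=vrec.ref or "N",
        alt_allele=alt,
        # htslib stores QUAL as float32; round away its representation noise
        qual=None if vrec.qual is None else round(vrec.qual, 3),
        filter=";".join(vrec.filter.keys()) or "PASS",
        info=residual,
        samples=samples,
        source_caller=caller,
        source_file=path,
    )
    return normalize_record(rec)


# ---------------------------------------------------------------------------
# writing

_INFO_HEADERS = [
    ('SVTYPE', '1', 'String', 'Type of structural variant'),
    ('END', '1', 'Integer', 'End position of the variant'),
    ('SVLEN', '1', 'Integer', 'Signed length of the variant'),
    ('CHR2', '1', 'String', 'Chromosome of the second breakpoint'),
    ('POS2', '1', 'Integer', 'Position of the second breakpoint'),
    ('STRANDS', '1', 'String', 'Breakpoint strand orientation pair'),
    ('MATEID', '1', 'String', 'ID of the mate breakend'),
    ('SUBTYPE', '1', 'String', 'Translocation subtype (balanced/unbalanced/merging)'),
    ('SUPP', '1', 'Integer', 'Number of supporting callers'),
    ('SUPP_CALLERS', '1', 'String', 'Comma-separated supporting callers'),
    ('CALLER', '1', 'String', 'Source caller of this record'),
]

_FORMAT_HEADERS = [
    ('GT', '1', 'String', 'Genotype'),
    ('AD', 'R', 'Integer', 'Read depth per allele'),
    ('DP', '1', 'Integer', 'Total read depth'),
    ('GQ', '1', 'Integer', 'Genotype quality'),
]


def _build_header(records: Sequence[SVRecord], sample_names: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    contigs: list[str] = []
    filters: set[str] = set()
    residual_keys: set[str] = set()
    for rec in records:
        for c in (rec.chrom, rec.chrom2):
            if c is not None and c not in contigs:
                contigs.append(c)
        for f in rec.filter.split(";"):
            if f not in ("PASS", "."):
                filters.add(f)
        residual_keys.update(k for k in rec.info
                             if k not in {h[0] for h in _INFO_HEADERS})
    for c in sorted(contigs):
        header.contigs.add(c)
    for name, number, typ, desc in _INFO_HEADERS:
        header.info.add(name, number, typ, desc)
    for key in sorted(residual_keys):
        header.info.add(key, '1', 'String', 'Carried-through annotation')
    for name, number, typ, desc in _FORMAT_HEADERS:
        header.formats.add(name, number, typ, desc)
    for f in sorted(filters):
        header.filters.add(f, None, None, 'Caller-assigned filter')
    for s in sample_names:
        header.add_sample(s)
    return header


def _alt_for(rec: SVRecord) -> str:
    if rec.svtype is SVType.BND:
        return rec.alt_allele or f"N[{rec.chrom2}:{rec.pos2}["
    return f"<{rec.svtype.value}>"


def _fill_sample(vsample, call: GenotypeCall) -> None:
    gt = call.gt.replace("|", "/").split("/")
    vsample["GT"] = tuple(None if a == "." else int(a) for a in gt)
    vsample.phased = "|" in call.gt
    if call.ad is not None:
        vsample["AD"] = call.ad
    if call.dp is not None:
        vsample["DP"] = call.dp
    if call.gq is not None:
        vsample["GQ"] = call.gq


def write_vcf(
    records: Iterable[SVRecord],
    path: str | Path,
    sample_names: Optional[Sequence[str]] = None,
) -> None:
    """Write normalized records as standard-compliant VCF.

    Every INFO/FORMAT tag emitted is declared in the header. TRA records are
    written with a symbolic ALT plus CHR2/POS2; BND records keep their bracket
    ALT. Records missing a listed sample get a ``./.`` call.
    """
    records = list(records)
    if sample_names is None:
        seen: list[str] = []
        for rec in records:
            for s in rec.samples:
                if s not in seen:
                    seen.append(s)
        sample_names = seen
    header = _build_header(records, sample_names)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            if (rec.end is not None and rec.end > rec.pos
                    and rec.svtype not in (SVType.TRA, SVType.BND)):
                stop = rec.end
            else:
                stop = rec.pos
            vrec = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                stop=stop,
                alleles=(rec.ref_allele, _alt_for(rec)),
                id=rec.record_id,
                qual=rec.qual,
            )
            for f in rec.filter.split(";"):
                vrec.filter.add(f if f != "." else "PASS")
            vrec.info["SVTYPE"] = rec.svtype.value
            if rec.svlen is not None:
                vrec.info["SVLEN"] = rec.svlen
            if rec.chrom2 is not None:
                vrec.info["CHR2"] = rec.chrom2
            if rec.pos2 is not None:
                vrec.info["POS2"] = rec.pos2
            if rec.strands != "..":
                vrec.info["STRANDS"] = rec.strands
            if rec.source_caller:
                vrec.info["CALLER"] = rec.source_caller
            for key, val in rec.info.items():
                if val != "":
                    vrec.info[key] = str(val)
            for s in sample_names:
                call = rec.samples.get(s, GenotypeCall())
                _fill_sample(vrec.samples[s], call)
            out.write(vrec)
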