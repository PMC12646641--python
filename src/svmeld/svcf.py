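"""SVCF: the tool's versioned tab-separated serialization of SVRecord.

One row per SV, lossless for every SVRecord field including caller-support
annotations added by merging. Layout (tab-separated)::

    ##fileformat=SVCFv1.0
    #CHROM POS ID REF ALT QUAL FILTER SVTYPE END SVLEN CHR2 POS2 STRANDS \
      SOURCE SOURCE_FILE INFO FORMAT <sample...>

Missing values are ``.``; INFO is ``key=value`` pairs joined by ``;``;
FORMAT is fixed to ``GT:AD:DP:GQ`` with AD printed ``ref,var``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

from .records import GenotypeCall, SVRecord, SVType

SVCF_VERSION = "1.0"

_FIXED_COLS = [
    "#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "SVTYPE",
    "END", "SVLEN", "CHR2", "POS2", "STRANDS", "SOURCE", "SOURCE_FILE",
    "INFO", "FORMAT",
]


class UnsupportedVersionError(ValueError):
    """The file's SVCF version stamp is missing or incompatible."""


def _dot(value) -> str:
    if value is None or value == "":
        return "."
    if isinstance(value, float):
        return format(value, ".10g")
    return str(value)


def _fmt_call(call: Optional[GenotypeCall]) -> str:
    if call is None:
        return "."
    ad = "." if call.ad is None else f"{call.ad[0]},{call.ad[1]}"
    return ":".join([call.gt, ad, _dot(call.dp), _dot(call.gq)])


def _parse_call(text: str) -> Optional[GenotypeCall]:
    if text == ".":
        return None
    gt, ad, dp, gq = text.split(":")
    pair = None if ad == "." else tuple(int(x) for x in ad.split(","))
    return GenotypeCall(
        gt=gt,
        ad=pair,
        dp=None if dp == "." else int(dp),
        gq=None if gq == "." else int(gq),
    )


def write_svcf(records: Iterable[SVRecord], path: str | Path) -> None:
    records = list(records)
    sample_names: list[str] = []
    for rec in records:
        for s in rec.samples:
            if s not in sample_names:
                sample_names.append(s)
    with open(path, "w") as out:
        out.write(f"##fileformat=SVCFv{SVCF_VERSION}\n")
        out.write("\t".join(_FIXED_COLS + sample_names) + "\n")
        for rec in records:
            info = ";".join(f"{k}={v}" for k, v in rec.info.items()) or "."
            row = [
                rec.chrom, str(rec.pos), rec.record_id, rec.ref_allele,
                _dot(rec.alt_allele), _dot(rec.qual), rec.filter,
                rec.svtype.value, _dot(rec.end), _dot(rec.svlen),
                _dot(rec.chrom2), _dot(rec.pos2), rec.strands,
                _dot(rec.source_caller), _dot(rec.source_file), info, "GT:AD:DP:GQ",
            ]
            row += [_fmt_call(rec.samples.get(s)) for s in sample_names]
            out.write("\t".join(row) + "\n")


def read_svcf(path: str | Path) -> list[SVRecord]:
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("##fileformat=SVCFv"):
            raise UnsupportedVersionError(f"{path}: missing SVCF version stamp")
        version = first.split("SVCFv", 1)[1]
        if version.split(".")[0] != SVCF_VERSION.split(".")[0]:
            raise UnsupportedVersionError(
                f"{path}: SVCF version {version} not supported (expected {SVCF_VERSION})"
            )
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_FIXED_COLS)] != _FIXED_COLS:
            raise UnsupportedVersionError(f"{path}: unexpected SVCF column layout")
        sample_names = header[len(_FIXED_COLS):]
        records = []
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            fixed = fields[: len(_FIXED_COLS)]
            calls = fields[len(_FIXED_COLS):]
            (chrom, pos, rid, ref, alt, qual, filt, svtype, end, svlen,
             chrom2, pos2, strands, source, source_file, info, _fmt) = fixed
            info_map = {}
            if info != ".":
                for pair in info.split(";"):
                    k, _, v = pair.partition("=")
                    info_map[k] = v
            samples = {}
            for name, text in zip(sample_names, calls):
                call = _parse_call(text)
                if call is not None:
                    samples[name] = call
            records.append(
                SVRecord(
                    record_id=rid,
                    chrom=chrom,
                    pos=int(pos),
                    svtype=SVType(svtype),
                    end=None if end == "." else int(end),
                    svlen=None if svlen == "." else int(svlen),
                    chrom2=None if chrom2 == "." else chrom2,
                    pos2=None if pos2 == "." else int(pos2),
                    strands=strands,
                    ref_allele=ref,
                    alt_allele="" if alt == "." else alt,
                    qual=None if qual == "." else float(qual),
                    filter=filt,
                    info=info_map,
                    samples=samples,
                    source_caller="" if source == "." else source,
                    source_file="" if source_file == "." else source_file,
                )
            )
    return records
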