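from __future__ import annotations

import pytest

from svmeld.records import GenotypeCall, SVRecord, SVType


def mk_sv(
    rid="r1",
    chrom="chr1",
    pos=1000,
    svtype="DEL",
    end=None,
    svlen=None,
    chrom2=None,
    pos2=None,
    strands=None,
    caller="c1",
    gt="0/1",
    ad=None,
    dp=None,
    gq=None,
    qual=None,
    sample="S",
    **kwargs,
) -> SVRecord:
    """Small-footprint SVRecord builder for tests."""
    svtype = SVType(svtype)
    if svtype in (SVType.DEL, SVType.DUP, SVType.INV):
        if end is None and svlen is not None:
            end = pos + abs(svlen)
        if svlen is None and end is not None:
            svlen = -(end - pos) if svtype is SVType.DEL else end - pos
    if strands is None:
        strands = {"DEL": "+-", "DUP": "-+", "INV": "++"}.get(svtype.value, "..")
    return SVRecord(
        record_id=rid,
        chrom=chrom,
        pos=pos,
        svtype=svtype,
        end=end,
        svlen=svlen,
        chrom2=chrom2,
        pos2=pos2,
        strands=strands,
        qual=qual,
        samples={sample: GenotypeCall(gt=gt, ad=ad, dp=dp, gq=gq)},
        source_caller=caller,
        **kwargs,
    )


@pytest.fixture
def mk():
    return mk_sv


def write_raw_vcf(path, body_lines, extra_header=(), samples=("S",)):
    """Write a minimal VCF by hand for parser tests (the one place raw text
    beats the library writer: we need to exercise foreign dialects)."""
    header = [
        "##fileformat=VCFv4.2",
        '##contig=<ID=chr1,length=10000000>',
        '##contig=<ID=chr2,length=10000000>',
        '##contig=<ID=chr5,length=10000000>',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="t">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="t">',
        '##INFO=<ID=CHR2,Number=1,Type=String,Description="t">',
        '##INFO=<ID=STRANDS,Number=1,Type=String,Description="t">',
        '##INFO=<ID=CT,Number=1,Type=String,Description="t">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="t">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="t">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="t">',
        '##FORMAT=<ID=DR,Number=1,Type=Integer,Description="t">',
        '##FORMAT=<ID=DV,Number=1,Type=Integer,Description="t">',
        *extra_header,
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        for line in body_lines:
            fh.write(line + "\n")
    return path
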