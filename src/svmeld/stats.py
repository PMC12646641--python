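"""Plain-text / JSON callset summaries (counts per type, per chromosome,
size histogram)."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .records import SVRecord

SIZE_BIN_EDGES = [0, 50, 100, 500, 1_000, 5_000, 10_000, 50_000, 100_000, float("inf")]


def _bin_label(lo: float, hi: float) -> str:
    if hi == float("inf"):
        return f">={int(lo)}"
    return f"[{int(lo)},{int(hi)})"


def summarize(records: Sequence[SVRecord]) -> dict:
    """Counts per SV type, per chromosome, and a size histogram.

    Type and chromosome counts each sum to the record total; events with no
    defined size (TRA/BND) are counted in ``no_size`` instead of a bin.
    """
    by_type: dict[str, int] = {}
    by_chrom: dict[str, int] = {}
    sizes = []
    no_size = 0
    for rec in records:
        by_type[rec.svtype.value] = by_type.get(rec.svtype.value, 0) + 1
        by_chrom[rec.chrom] = by_chrom.get(rec.chrom, 0) + 1
        if rec.size is None:
            no_size += 1
        else:
            sizes.append(rec.size)
    hist, _ = np.histogram(sizes, bins=SIZE_BIN_EDGES) if sizes else (
        np.zeros(len(SIZE_BIN_EDGES) - 1, dtype=int), None)
    size_hist = {
        _bin_label(SIZE_BIN_EDGES[i], SIZE_BIN_EDGES[i + 1]): int(hist[i])
        for i in range(len(hist))
    }
    return {
        "total": len(records),
        "by_type": dict(sorted(by_type.items())),
        "by_chrom": dict(sorted(by_chrom.items())),
        "size_histogram": size_hist,
        "no_size": no_size,
    }
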