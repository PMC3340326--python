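"""QTL intervals and the trait's QTL gene set Q.

A QTL record gives either a flanking-marker interval or only a peak
position; when flanks are unknown the interval falls back to peak ± 20 Mb.
Q is the union, over all of a trait's intervals, of genes whose transcript
span (1-based closed) intersects an interval on the same chromosome.
Single-base touching counts as overlap — the inclusive choice for candidate
capture.  Intervals are not clamped at chromosome ends (chromosome sizes
are not an input) and are not merged; Q is a set union so duplicates are
harmless.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import GeneAnnotation, QTLRecord

#: half-width of the fallback interval around a peak marker, in bp
DEFAULT_FALLBACK_HALFWIDTH_BP = 20_000_000


@dataclass(frozen=True)
class QTLInterval:
    """A trait-linked genomic interval, 1-based closed."""

    qtl_name: str
    trait: str
    chromosome: str
    start_bp: int
    end_bp: int

    def __post_init__(self):
        if not 0 <= self.start_bp <= self.end_bp:
            raise ValueError(
                f"QTL {self.qtl_name!r}: invalid interval [{self.start_bp}, {self.end_bp}]"
            )


def build_qtl_interval(
    record: QTLRecord, fallback_halfwidth_bp: int = DEFAULT_FALLBACK_HALFWIDTH_BP
) -> QTLInterval:
    """Interval from flanking markers, else peak ± halfwidth (clamped at 0)."""
    if record.flank_start_bp is not None and record.flank_end_bp is not None:
        start, end = record.flank_start_bp, record.flank_end_bp
    else:
        start = max(0, record.peak_bp - fallback_halfwidth_bp)
        end = record.peak_bp + fallback_halfwidth_bp
    return QTLInterval(record.qtl_name, record.trait, record.chromosome, start, end)


def build_qtl_intervals(
    records: Iterable[QTLRecord],
    trait: str | None = None,
    fallback_halfwidth_bp: int = DEFAULT_FALLBACK_HALFWIDTH_BP,
) -> list[QTLInterval]:
    """Build intervals for all records, optionally restricted to one trait."""
    return [
        build_qtl_interval(r, fallback_halfwidth_bp)
        for r in records
        if trait is None or r.trait == trait
    ]


def genes_in_qtl(
    annotations: Sequence[GeneAnnotation], intervals: Sequence[QTLInterval]
) -> set[str]:
    """The QTL gene set Q: genes whose transcript overlaps any interval.

    Overlap on closed intervals: gene.start <= interval.end and
    gene.end >= interval.start, on the same chromosome.
    """
    by_chrom: dict[str, list[QTLInterval]] = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chromosome].append(iv)

    q: set[str] = set()
    genes_by_chrom: dict[str, list[GeneAnnotation]] = defaultdict(list)
    for a in annotations:
        genes_by_chrom[a.chromosome].append(a)

    for chrom, ivs in by_chrom.items():
        genes = genes_by_chrom.get(chrom)
        if not genes:
            continue
        g_start = np.array([g.start_bp for g in genes])
        g_end = np.array([g.end_bp for g in genes])
        hit = np.zeros(len(genes), dtype=bool)
        for iv in ivs:
            hit |= (g_start <= iv.end_bp) & (g_end >= iv.start_bp)
        q.update(genes[i].gene_id for i in np.nonzero(hit)[0])
    return q
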