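"""In-silico downsampling of WGS calls to whole-exome resolution.

Mutations and indels are kept only when they touch an exome target
interval; allele-specific CN segments are kept (unchanged, with their
original genomic coordinates and size) when they overlap at least one
target base, because the CN-48 size bins describe genomic, not captured,
extent. A ``clip`` mode that intersects segment coordinates with the
target footprint is available for comparison.

Targets are BED-style: 0-based, half-open. Chromosome names are
normalized by stripping any ``chr`` prefix on both sides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .records import CNSegment, IndelRecord, MutationRecord

logger = logging.getLogger(__name__)


def _norm_chrom(name: str) -> str:
    return name[3:] if name.lower().startswith("chr") else name


@dataclass
class IntervalSet:
    """Sorted, merged half-open intervals keyed by chromosome."""

    _starts: dict[str, np.ndarray] = field(default_factory=dict)
    _ends: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[tuple[str, int, int]]
    ) -> "IntervalSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if end <= start:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            by_chrom.setdefault(_norm_chrom(chrom), []).append((start, end))
        iset = cls()
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            merged: list[list[int]] = []
            for start, end in pairs:
                if merged and start <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], end)
                else:
                    merged.append([start, end])
            iset._starts[chrom] = np.array([m[0] for m in merged])
            iset._ends[chrom] = np.array([m[1] for m in merged])
        return iset

    def overlaps(self, chromosome: str, start: int, end: int) -> bool:
        """True iff [start, end) intersects any interval on the chromosome."""
        chrom = _norm_chrom(chromosome)
        if chrom not in self._starts:
            return False
        starts, ends = self._starts[chrom], self._ends[chrom]
        idx = int(np.searchsorted(starts, end, side="left"))
        return idx > 0 and ends[idx - 1] > start

    def overlap_bp(self, chromosome: str, start: int, end: int) -> int:
        """Total overlapping bases between [start, end) and the set."""
        chrom = _norm_chrom(chromosome)
        if chrom not in self._starts:
            return 0
        starts, ends = self._starts[chrom], self._ends[chrom]
        lo = np.maximum(starts, start)
        hi = np.minimum(ends, end)
        return int(np.maximum(hi - lo, 0).sum())

    def total_bp(self) -> int:
        return int(
            sum((e - s).sum() for s, e in zip(self._starts.values(), self._ends.values()))
        )

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self._starts):
            for s, e in zip(self._starts[chrom], self._ends[chrom]):
                out.append((chrom, int(s), int(e)))
        return out


def read_bed(path) -> IntervalSet:
    """Read target intervals from a BED file (first three columns)."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            intervals.append((chrom, int(start), int(end)))
    return IntervalSet.from_intervals(intervals)


def _event_span(record: MutationRecord | IndelRecord) -> tuple[int, int]:
    """Half-open genomic footprint of an event (1-based positions in)."""
    if isinstance(record, IndelRecord) and record.kind == "deletion":
        return record.position - 1, record.position - 1 + len(record.sequence)
    return record.position - 1, record.position


def restrict_mutations(
    records: Sequence[MutationRecord | IndelRecord], targets: IntervalSet
) -> list:
    """Keep mutations/indels whose affected bases touch a target interval."""
    kept = []
    for rec in records:
        start, end = _event_span(rec)
        if targets.overlaps(rec.chromosome, start, end):
            kept.append(rec)
    return kept


def restrict_segments(
    segments: Sequence[CNSegment], targets: IntervalSet, clip: bool = False
) -> list[CNSegment]:
    """Keep CN segments overlapping at least one target base.

    With ``clip=False`` (default) segments keep their original coordinates;
    with ``clip=True`` each kept segment is truncated to the bounding range
    of its on-target footprint.
    """
    kept = []
    for seg in segments:
        if not targets.overlaps(seg.chromosome, seg.start, seg.end):
            continue
        if not clip:
            kept.append(seg)
            continue
        chrom = _norm_chrom(seg.chromosome)
        starts = targets._starts[chrom]
        ends = targets._ends[chrom]
        inside = (starts < seg.end) & (ends > seg.start)
        new_start = int(max(seg.start, starts[inside].min()))
        new_end = int(min(seg.end, ends[inside].max()))
        kept.append(
            CNSegment(
                sample_id=seg.sample_id,
                chromosome=seg.chromosome,
                start=new_start,
                end=new_end,
                major_cn=seg.major_cn,
                minor_cn=seg.minor_cn,
            )
        )
    return kept
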