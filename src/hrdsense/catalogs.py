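"""Classify mutations, indels and CN segments into canonical channels.

Implements the three channel classifiers (SBS-96, ID-83, CN-48) and
``build_catalogs``, which aggregates per-sample channel count vectors.

Classification rules
--------------------
* Substitutions are strand-collapsed to the pyrimidine representation: a
  purine reference base is reverse-complemented together with both context
  bases before naming, so ``classify_sbs`` is invariant under reverse
  complement of the whole record.
* Indels follow the COSMIC ID-83 conventions. Repeat-unit counts are the
  number of additional whole copies of the event sequence found contiguously
  in the 3' and 5' flanks (summed, capped at the 5+ bucket). Deletions of
  length >= 2 with no adjacent full copy are assigned a microhomology
  category when the deleted sequence shares a partial prefix with the 3'
  flank or a partial suffix with the 5' flank (the longer of the two, capped
  at 5 bp); repeat context takes precedence over microhomology.
* CN segments are named by TCN class x zygosity x size bin. LOH means
  minor_cn = 0 with at least one retained copy; homozygous deletions
  (TCN = 0) use their own reduced size bins. Size bins are left-open /
  right-closed, so a segment of exactly 40 Mb falls in the 10-40Mb bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .records import ClassificationError, CNSegment, IndelRecord, MutationRecord
from .schemas import CN48, COMPLEMENT, ID83, SBS96

logger = logging.getLogger(__name__)

_MITO_NAMES = frozenset({"M", "MT", "CHRM", "CHRMT"})

_PYRIMIDINE_OF = {"A": "T", "G": "C", "C": "C", "T": "T"}


def classify_sbs(record: MutationRecord) -> str:
    """Map a substitution to its SBS-96 channel name, e.g. ``A[C>T]G``."""
    ref, alt = record.ref_base, record.alt_base
    c5, c3 = record.context5, record.context3
    if ref in "AG":  # purine reference: reverse-complement mutation and flanks
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        c5, c3 = COMPLEMENT[c3], COMPLEMENT[c5]
    return f"{c5}[{ref}>{alt}]{c3}"


def _count_adjacent_copies(motif: str, flank3: str, flank5: str, cap: int = 5) -> int:
    """Whole copies of ``motif`` contiguous with the event site.

    Scans the 3' flank left-to-right and the 5' flank right-to-left. Raises
    if a flank is exhausted mid-scan while the count is still below the cap
    (the bucket would be ambiguous).
    """
    unit = len(motif)
    count = 0
    pos = 0
    while count < cap and flank3[pos : pos + unit] == motif:
        count += 1
        pos += unit
    if count < cap and len(flank3) - pos < unit and flank3[pos:] == motif[: len(flank3) - pos]:
        raise ClassificationError(
            f"3' flank too short to resolve the repeat count for motif {motif!r};"
            " provide longer context"
        )
    pos = len(flank5)
    while count < cap and pos >= unit and flank5[pos - unit : pos] == motif:
        count += 1
        pos -= unit
    if count < cap and pos < unit and flank5[:pos] == motif[unit - pos :]:
        raise ClassificationError(
            f"5' flank too short to resolve the repeat count for motif {motif!r};"
            " provide longer context"
        )
    return count


def _microhomology_length(seq: str, flank3: str, flank5: str, cap: int = 5) -> int:
    """Longest partial-copy overlap between a deleted sequence and its flanks."""
    mh3 = 0
    while mh3 < min(len(seq) - 1, len(flank3), cap) and seq[mh3] == flank3[mh3]:
        mh3 += 1
    mh5 = 0
    while (
        mh5 < min(len(seq) - 1, len(flank5), cap)
        and seq[-1 - mh5] == flank5[-1 - mh5]
    ):
        mh5 += 1
    return max(mh3, mh5)


def classify_indel(record: IndelRecord) -> str:
    """Map an insertion/deletion to its ID-83 channel name, e.g. ``5:Del:M:3``."""
    seq = record.sequence
    length = len(seq)
    record.require_flanks(min(length, 5))
    op = "Del" if record.kind == "deletion" else "Ins"
    if length == 1:
        copies = _count_adjacent_copies(seq, record.flank3, record.flank5)
        base = _PYRIMIDINE_OF[seq]
        if record.kind == "deletion":
            return f"1:Del:{base}:{min(copies, 5)}"
        return f"1:Ins:{base}:{min(copies, 5)}"
    size_label = min(length, 5)
    copies = _count_adjacent_copies(seq, record.flank3, record.flank5)
    if record.kind == "insertion" or copies >= 1:
        return f"{size_label}:{op}:R:{min(copies, 5)}"
    mh = _microhomology_length(seq, record.flank3, record.flank5)
    if mh >= 1:
        return f"{size_label}:Del:M:{min(mh, 5)}"
    return f"{size_label}:Del:R:0"


_SIZE_EDGES = (100_000, 1_000_000, 10_000_000, 40_000_000)
_SIZE_LABELS = ("0-100kb", "100kb-1Mb", "1-10Mb", "10-40Mb", ">40Mb")


def _size_bin(size: int, edges: Sequence[int], labels: Sequence[str]) -> str:
    for edge, label in zip(edges, labels):
        if size <= edge:
            return label
    return labels[len(edges)]


def _tcn_class(tcn: int) -> str:
    if tcn <= 2:
        return str(tcn)
    if tcn <= 4:
        return "3-4"
    if tcn <= 8:
        return "5-8"
    return "9+"


def classify_cn_segment(segment: CNSegment) -> str:
    """Map an allele-specific CN segment to its CN-48 channel name."""
    tcn = segment.total_cn
    size = segment.size_bp
    if tcn == 0:
        label = _size_bin(size, _SIZE_EDGES[:2], ("0-100kb", "100kb-1Mb", ">1Mb"))
        return f"0:HomDel:{label}"
    zygosity = "LOH" if segment.minor_cn == 0 else "HET"
    return f"{_tcn_class(tcn)}:{zygosity}:{_size_bin(size, _SIZE_EDGES, _SIZE_LABELS)}"


@dataclass
class ChannelCatalog:
    """Per-sample channel count vectors over the three canonical schemas."""

    sample_id: str
    sbs96: pd.Series = field(default_factory=lambda: _zeros(SBS96))
    id83: pd.Series = field(default_factory=lambda: _zeros(ID83))
    cn48: pd.Series = field(default_factory=lambda: _zeros(CN48))

    def counts(self, channel_class: str) -> pd.Series:
        return getattr(self, channel_class)

    def proportions(self, channel_class: str) -> pd.Series:
        """Channel proportions within one class; zero vector if no events."""
        counts = self.counts(channel_class)
        total = counts.sum()
        if total == 0:
            return counts.astype(float)
        return counts / total


def _zeros(names: Sequence[str]) -> pd.Series:
    return pd.Series(0, index=list(names), dtype=int)


def _is_mito(chromosome: str) -> bool:
    return chromosome.upper() in _MITO_NAMES


def build_catalogs(
    mutations: Iterable[MutationRecord] = (),
    indels: Iterable[IndelRecord] = (),
    segments: Iterable[CNSegment] = (),
) -> list[ChannelCatalog]:
    """Aggregate records into one :class:`ChannelCatalog` per sample.

    Samples present in any of the three inputs appear exactly once, sorted by
    sample id; channels without events count zero. Mitochondrial records are
    dropped with a warning. The per-class vector sums equal the number of
    classified events of that type for the sample.
    """
    counts: dict[str, dict[str, dict[str, int]]] = {}
    n_mito = 0

    def bucket(sample_id: str, channel_class: str) -> dict[str, int]:
        return counts.setdefault(
            sample_id, {"sbs96": {}, "id83": {}, "cn48": {}}
        )[channel_class]

    for rec in mutations:
        if _is_mito(rec.chromosome):
            n_mito += 1
            continue
        ch = classify_sbs(rec)
        b = bucket(rec.sample_id, "sbs96")
        b[ch] = b.get(ch, 0) + 1
    for rec in indels:
        if _is_mito(rec.chromosome):
            n_mito += 1
            continue
        ch = classify_indel(rec)
        b = bucket(rec.sample_id, "id83")
        b[ch] = b.get(ch, 0) + 1
    for seg in segments:
        if _is_mito(seg.chromosome):
            n_mito += 1
            continue
        ch = classify_cn_segment(seg)
        b = bucket(seg.sample_id, "cn48")
        b[ch] = b.get(ch, 0) + 1

    if n_mito:
        logger.warning("dropped %d mitochondrial records", n_mito)

    catalogs = []
    for sample_id in sorted(counts):
        cat = ChannelCatalog(sample_id)
        for channel_class, names in (("sbs96", SBS96), ("id83", ID83), ("cn48", CN48)):
            per = counts[sample_id][channel_class]
            if per:
                series = _zeros(names)
                for name, value in per.items():
                    series[name] = value
                setattr(cat, channel_class, series)
        catalogs.append(cat)
    return catalogs


def catalogs_to_frame(catalogs: Sequence[ChannelCatalog], channel_class: str) -> pd.DataFrame:
    """Channels x samples count matrix for one channel class."""
    names = list(CHANNEL_NAMES[channel_class])
    data = {c.sample_id: c.counts(channel_class).reindex(names) for c in catalogs}
    frame = pd.DataFrame(data, index=names)
    frame.index.name = "channel"
    return frame


CHANNEL_NAMES = {"sbs96": SBS96, "id83": ID83, "cn48": CN48}
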