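"""Domain records: substitutions, indels and allele-specific CN segments.

Records carry enough local sequence context to be classified without access
to a reference genome: substitutions carry their immediate 5'/3' bases and
indels carry >=25 bp flanks so repeat counts (up to the schema's 5+ bucket)
and microhomology (up to 5 bp) can always be resolved.

Coordinate conventions
----------------------
Mutation/indel positions are 1-based. For a deletion, ``position`` is the
first deleted base; for an insertion it is the base immediately 5' of the
insertion point. CN segments are stored 0-based half-open, so
``size_bp = end - start``; the ASCAT-style TSV reader converts from 1-based
inclusive coordinates on input.
"""

from __future__ import annotations

from dataclasses import dataclass

_VALID_BASES = frozenset("ACGT")

MIN_FLANK = 25


class ClassificationError(ValueError):
    """An input record cannot be mapped to a channel."""


def _check_base(base: str, what: str, record: object) -> None:
    if base not in _VALID_BASES:
        raise ClassificationError(f"invalid {what} {base!r} in record {record}")


def _check_seq(seq: str, what: str, record: object) -> None:
    if not seq or any(b not in _VALID_BASES for b in seq):
        raise ClassificationError(f"invalid {what} {seq!r} in record {record}")


@dataclass(frozen=True)
class MutationRecord:
    """One somatic single-base substitution."""

    sample_id: str
    chromosome: str
    position: int
    ref_base: str
    alt_base: str
    context5: str
    context3: str

    def __post_init__(self) -> None:
        for base, what in (
            (self.ref_base, "ref base"),
            (self.alt_base, "alt base"),
            (self.context5, "5' context"),
            (self.context3, "3' context"),
        ):
            _check_base(base, what, self)
        if self.ref_base == self.alt_base:
            raise ClassificationError(f"ref equals alt in record {self}")


@dataclass(frozen=True)
class IndelRecord:
    """One somatic small insertion or deletion with flanking sequence."""

    sample_id: str
    chromosome: str
    position: int
    kind: str  # "insertion" | "deletion"
    sequence: str  # inserted or deleted bases
    flank5: str  # upstream sequence, 3'-most base adjacent to the event
    flank3: str  # downstream sequence, 5'-most base adjacent to the event

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise ClassificationError(f"invalid indel kind {self.kind!r}")
        _check_seq(self.sequence, "indel sequence", self)
        _check_seq(self.flank5, "5' flank", self)
        _check_seq(self.flank3, "3' flank", self)

    def require_flanks(self, needed: int) -> None:
        if len(self.flank5) < needed or len(self.flank3) < needed:
            raise ClassificationError(
                f"flanks shorter than {needed} bp cannot resolve the channel for "
                f"{self.sample_id}:{self.chromosome}:{self.position}; provide "
                f"at least {MIN_FLANK} bp of context on both sides"
            )


@dataclass(frozen=True)
class CNSegment:
    """One allele-specific copy-number segment (half-open coordinates)."""

    sample_id: str
    chromosome: str
    start: int
    end: int
    major_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.major_cn < 0 or self.minor_cn < 0:
            raise ClassificationError(f"negative copy number in segment {self}")
        if self.major_cn < self.minor_cn:
            raise ClassificationError(
                f"major_cn < minor_cn in segment {self}; allele-specific calls "
                "must be ordered"
            )
        if self.end <= self.start:
            raise ClassificationError(f"empty or inverted segment {self}")

    @property
    def total_cn(self) -> int:
        return self.major_cn + self.minor_cn

    @property
    def size_bp(self) -> int:
        return self.end - self.start
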