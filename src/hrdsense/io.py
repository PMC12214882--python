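"""Readers and writers for the package's tab-separated file dialects.

Dialects
--------
Mutation TSV (SNVs and indels together), VCF-like minimal representation
with explicit flanking sequence so no reference genome is needed::

    sample  chrom  pos  ref  alt  flank5  flank3

* SNV: ``ref``/``alt`` single differing bases; ``pos`` is the mutated base
  (1-based); flanks are the sequences immediately 5'/3' of it (>= 1 bp).
* Deletion: ``ref = anchor + deleted``, ``alt = anchor``; ``pos`` is the
  anchor position; ``flank5`` ends with the anchor base and ``flank3``
  starts immediately after the deleted run (>= 25 bp flanks recommended).
* Insertion: ``ref = anchor``, ``alt = anchor + inserted``; same flank
  convention.
* Records with both multi-base ref and alt (complex) are skipped with a
  warning; the ID-83 schema does not cover them.

Segment TSV (ASCAT-style, 1-based inclusive coordinates in the file;
converted to half-open internally)::

    sample  chrom  start  end  major_cn  minor_cn

Catalog TSV: channels x samples, with leading ``channel_class`` and
``channel`` columns in the canonical channel ordering.

An optional VCF 4.x reader (requires pysam + a FASTA for flanks) accepts
standard somatic VCFs.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import pandas as pd

from .catalogs import CHANNEL_NAMES, ChannelCatalog, catalogs_to_frame
from .features import GroundTruthAnnotation
from .records import CNSegment, IndelRecord, MutationRecord
from .synthetic import SimulatedCohort

logger = logging.getLogger(__name__)

MUTATION_COLUMNS = ["sample", "chrom", "pos", "ref", "alt", "flank5", "flank3"]
SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "major_cn", "minor_cn"]


def write_mutation_tsv(
    path,
    mutations: Sequence[MutationRecord] = (),
    indels: Sequence[IndelRecord] = (),
) -> None:
    rows = []
    for rec in mutations:
        rows.append(
            (
                rec.sample_id,
                rec.chromosome,
                rec.position,
                rec.ref_base,
                rec.alt_base,
                rec.context5,
                rec.context3,
            )
        )
    for rec in indels:
        anchor = rec.flank5[-1]
        if rec.kind == "deletion":
            ref, alt, pos = anchor + rec.sequence, anchor, rec.position - 1
        else:
            ref, alt, pos = anchor, anchor + rec.sequence, rec.position
        rows.append(
            (rec.sample_id, rec.chromosome, pos, ref, alt, rec.flank5, rec.flank3)
        )
    frame = pd.DataFrame(rows, columns=MUTATION_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)


def read_mutation_tsv(path) -> tuple[list[MutationRecord], list[IndelRecord]]:
    frame = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    missing = set(MUTATION_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"mutation TSV {path} lacks columns {sorted(missing)}")
    mutations: list[MutationRecord] = []
    indels: list[IndelRecord] = []
    n_complex = 0
    for row in frame.itertuples(index=False):
        ref, alt = str(row.ref), str(row.alt)
        if len(ref) == 1 and len(alt) == 1:
            mutations.append(
                MutationRecord(
                    sample_id=row.sample,
                    chromosome=row.chrom,
                    position=int(row.pos),
                    ref_base=ref,
                    alt_base=alt,
                    context5=str(row.flank5)[-1],
                    context3=str(row.flank3)[0],
                )
            )
        elif len(ref) > 1 and len(alt) == 1 and ref[0] == alt:
            indels.append(
                IndelRecord(
                    sample_id=row.sample,
                    chromosome=row.chrom,
                    position=int(row.pos) + 1,
                    kind="deletion",
                    sequence=ref[1:],
                    flank5=str(row.flank5),
                    flank3=str(row.flank3),
                )
            )
        elif len(alt) > 1 and len(ref) == 1 and alt[0] == ref:
            indels.append(
                IndelRecord(
                    sample_id=row.sample,
                    chromosome=row.chrom,
                    position=int(row.pos),
                    kind="insertion",
                    sequence=alt[1:],
                    flank5=str(row.flank5),
                    flank3=str(row.flank3),
                )
            )
        else:
            n_complex += 1
    if n_complex:
        logger.warning(
            "skipped %d complex/multi-nucleotide records not covered by the "
            "SBS-96/ID-83 schemas",
            n_complex,
        )
    return mutations, indels


def write_segments_tsv(path, segments: Sequence[CNSegment]) -> None:
    rows = [
        (s.sample_id, s.chromosome, s.start + 1, s.end, s.major_cn, s.minor_cn)
        for s in segments
    ]
    pd.DataFrame(rows, columns=SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_segments_tsv(path) -> list[CNSegment]:
    frame = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    missing = set(SEGMENT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"segment TSV {path} lacks columns {sorted(missing)}")
    return [
        CNSegment(
            sample_id=row.sample,
            chromosome=row.chrom,
            start=int(row.start) - 1,  # 1-based inclusive -> half-open
            end=int(row.end),
            major_cn=int(row.major_cn),
            minor_cn=int(row.minor_cn),
        )
        for row in frame.itertuples(index=False)
    ]


def write_catalog_tsv(path, catalogs: Sequence[ChannelCatalog]) -> None:
    frames = []
    for channel_class in ("sbs96", "id83", "cn48"):
        frame = catalogs_to_frame(catalogs, channel_class).reset_index()
        frame.insert(0, "channel_class", channel_class)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_catalog_tsv(path) -> list[ChannelCatalog]:
    frame = pd.read_csv(path, sep="\t")
    samples = [c for c in frame.columns if c not in ("channel_class", "channel")]
    catalogs = []
    for sample in samples:
        cat = ChannelCatalog(str(sample))
        for channel_class in ("sbs96", "id83", "cn48"):
            sub = frame[frame["channel_class"] == channel_class]
            series = pd.Series(
                sub[sample].to_numpy(dtype=int), index=sub["channel"].tolist()
            )
            expected = list(CHANNEL_NAMES[channel_class])
            if list(series.index) != expected:
                series = series.reindex(expected, fill_value=0)
            setattr(cat, channel_class, series)
        catalogs.append(cat)
    return catalogs


def write_truth_tsv(
    path, annotations: Sequence[GroundTruthAnnotation], labels=None
) -> None:
    rows = []
    for ann in annotations:
        rows.append(
            {
                "sample": ann.sample_id,
                "hrd_score": ann.hrd_score if ann.hrd_score is not None else "",
                "brca_defect": int(ann.brca_defect),
                "cancer_type": ann.cancer_type or "",
                "label": labels[ann.sample_id] if labels is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> list[GroundTruthAnnotation]:
    frame = pd.read_csv(path, sep="\t", dtype={"sample": str})
    out = []
    for row in frame.itertuples(index=False):
        score = getattr(row, "hrd_score", None)
        out.append(
            GroundTruthAnnotation(
                sample_id=row.sample,
                hrd_score=None if pd.isna(score) else int(score),
                brca_defect=bool(getattr(row, "brca_defect", 0)),
                cancer_type=(
                    None
                    if pd.isna(getattr(row, "cancer_type", None))
                    else str(row.cancer_type)
                )
                or None,
            )
        )
    return out


def read_labels_tsv(path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if "label" not in frame.columns:
        raise ValueError(f"label TSV {path} needs a 'label' column")
    return pd.Series(frame["label"].tolist(), index=frame["sample"].tolist())


def write_bed(path, intervals: Iterable[tuple[str, int, int]]) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_predictions_tsv(
    path,
    sample_ids: Sequence[str],
    probabilities: Sequence[float],
    calls: Sequence[str],
    threshold: float,
    model_id: str,
) -> None:
    frame = pd.DataFrame(
        {
            "sample": list(sample_ids),
            "probability": [f"{p:.6f}" for p in probabilities],
            "label": list(calls),
            "threshold": threshold,
            "model_id": model_id,
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def write_cohort(directory, cohort: SimulatedCohort) -> dict[str, str]:
    """Write a simulated cohort's files into a directory; returns the paths."""
    import os

    os.makedirs(directory, exist_ok=True)
    paths = {
        "mutations": os.path.join(directory, "mutations.tsv"),
        "segments": os.path.join(directory, "segments.tsv"),
        "truth": os.path.join(directory, "truth.tsv"),
    }
    write_mutation_tsv(paths["mutations"], cohort.mutations, cohort.indels)
    write_segments_tsv(paths["segments"], cohort.segments)
    write_truth_tsv(paths["truth"], cohort.annotations, cohort.labels)
    return paths


def read_vcf(
    path, fasta: Optional[str] = None, sample_id: Optional[str] = None, flank: int = 30
) -> tuple[list[MutationRecord], list[IndelRecord]]:
    """Read SNVs and indels from a VCF 4.x file.

    Flanking sequence is taken from ``fasta`` (required; the TSV dialect is
    the self-contained alternative). ``sample_id`` defaults to the first
    sample in the VCF header, or the file stem for site-only VCFs.
    """
    import os

    try:
        import pysam
        from pyfaidx import Fasta
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF input requires pysam and pyfaidx") from exc
    if fasta is None:
        raise ValueError("a FASTA is required to derive flanks from a VCF")
    ref_genome = Fasta(fasta)
    vcf = pysam.VariantFile(str(path))
    if sample_id is None:
        samples = list(vcf.header.samples)
        sample_id = samples[0] if samples else os.path.basename(str(path)).split(".")[0]

    def fetch(chrom: str, start0: int, end0: int) -> str:
        start0 = max(start0, 0)
        return str(ref_genome[chrom][start0:end0]).upper()

    mutations: list[MutationRecord] = []
    indels: list[IndelRecord] = []
    for rec in vcf:
        ref = (rec.ref or "").upper()
        for alt in rec.alts or ():
            alt = alt.upper()
            pos = rec.pos  # 1-based
            if len(ref) == 1 and len(alt) == 1:
                mutations.append(
                    MutationRecord(
                        sample_id=sample_id,
                        chromosome=rec.chrom,
                        position=pos,
                        ref_base=ref,
                        alt_base=alt,
                        context5=fetch(rec.chrom, pos - 2, pos - 1),
                        context3=fetch(rec.chrom, pos, pos + 1),
                    )
                )
            elif len(ref) > 1 and len(alt) == 1 and ref[0] == alt:
                deleted = ref[1:]
                indels.append(
                    IndelRecord(
                        sample_id=sample_id,
                        chromosome=rec.chrom,
                        position=pos + 1,
                        kind="deletion",
                        sequence=deleted,
                        flank5=fetch(rec.chrom, pos - flank, pos),
                        flank3=fetch(
                            rec.chrom, pos + len(deleted), pos + len(deleted) + flank
                        ),
                    )
                )
            elif len(alt) > 1 and len(ref) == 1 and alt[0] == ref:
                indels.append(
                    IndelRecord(
                        sample_id=sample_id,
                        chromosome=rec.chrom,
                        position=pos,
                        kind="insertion",
                        sequence=alt[1:],
                        flank5=fetch(rec.chrom, pos - flank, pos),
                        flank3=fetch(rec.chrom, pos, pos + flank),
                    )
                )
            else:
                logger.warning(
                    "skipping complex variant %s:%d %s>%s", rec.chrom, pos, ref, alt
                )
    return mutations, indels
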