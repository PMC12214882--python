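"""Synthetic labeled cohorts with HRD/HRP-differential channel enrichments.

The generator draws per-sample channel counts from class-tilted multinomial
distributions and can emit concrete mutation/indel/segment records on a toy
genome whose flanking sequences realize the intended channel, so the channel
classifiers are exercised end-to-end.

Statistical structure
---------------------
Each channel class (SBS-96, ID-83, CN-48) has a baseline probability vector
loosely shaped like a quiet breast-cancer genome (CpG-transition mass
elevated among substitutions, T-homopolymer indels common, mostly diploid
heterozygous copy-number segments). For an HRD sample the probabilities of
the HRD-enriched channel groups (N[C>G]T substitutions, 5 bp+ microhomology
deletions, 1-40 Mb LOH, TCN 3-9 heterozygous 10-40 Mb segments) are scaled
up by the configured effect sizes; for an HRP sample the HRP-enriched groups
(N[C>T]G substitutions, TCN 2-4 heterozygous >40 Mb segments) are scaled up.
After tilting, each sample's probability vector is jittered with a Dirichlet
draw (concentration x probabilities) and event counts are drawn
multinomially at the configured burden, so per-channel counts sum to the
burden exactly.

Default effect sizes are chosen so that cohort-level log2 fold changes land
around 1-1.5, comfortably clearing the whole-genome volcano-selection
threshold of 0.75. The default Dirichlet concentration of 500 gives
moderate inter-sample variability (per-sample channel-proportion CV of
roughly 30-50% for channels near 1%), enough to jitter individual samples
while keeping 100-sample group means stable to a few percent. Setting every
effect size to 1 yields exchangeable groups (the null cohort).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .catalogs import ChannelCatalog
from .features import GroundTruthAnnotation
from .records import CNSegment, IndelRecord, MutationRecord
from .schemas import (
    BASES,
    CN48,
    COMPLEMENT,
    ID83,
    SBS96,
    feature_channels,
    reverse_complement,
)

#: Toy genome: three 60 Mb chromosomes; flanks are generated per event.
TOY_CHROMOSOMES = {"1": 60_000_000, "2": 60_000_000, "3": 60_000_000}

_FLANK_LEN = 30


@dataclass(frozen=True)
class EffectSizes:
    """Multiplicative channel-probability enrichments (>= 1)."""

    nctg_hrp: float = 2.0  # N[C>T]G substitutions, up in HRP
    ncgt_hrd: float = 2.0  # N[C>G]T substitutions, up in HRD
    del5_mh_hrd: float = 3.0  # 5:Del:M:1-5 deletions, up in HRD
    loh_1_40_hrd: float = 2.5  # LOH 1-40 Mb segments, up in HRD
    het3_9_10_40_hrd: float = 2.0  # TCN 3-9 HET 10-40 Mb, up in HRD
    het2_4_gt40_hrp: float = 2.0  # TCN 2-4 HET >40 Mb, up in HRP

    def null(self) -> "EffectSizes":
        return EffectSizes(1.0, 1.0, 1.0, 1.0, 1.0, 1.0)


@dataclass(frozen=True)
class SimulationConfig:
    n_hrd: int = 100
    n_hrp: int = 100
    sbs_burden: int = 5000
    indel_burden: int = 250
    n_segments: int = 100
    effects: EffectSizes = field(default_factory=EffectSizes)
    dirichlet_concentration: float = 500.0
    assay: str = "WGS"
    cancer_type: str = "breast"
    sample_prefix: str = "S"
    seed: int = 0

    def null(self) -> "SimulationConfig":
        return replace(self, effects=self.effects.null())


#: Whole-exome burden preset (~1% of the genome footprint).
WES_PRESET = {"sbs_burden": 80, "indel_burden": 15, "n_segments": 60}


def wes_config(**overrides) -> SimulationConfig:
    return SimulationConfig(assay="WES", **{**WES_PRESET, **overrides})


@dataclass
class SimulatedCohort:
    mutations: list[MutationRecord]
    indels: list[IndelRecord]
    segments: list[CNSegment]
    labels: pd.Series  # sample -> "HRD" | "HRP"
    annotations: list[GroundTruthAnnotation]
    config: SimulationConfig


def _baseline_sbs() -> np.ndarray:
    probs = np.ones(len(SBS96))
    cpg = set(feature_channels("n_ct_g"))
    for i, name in enumerate(SBS96):
        if name in cpg:
            probs[i] *= 4.0  # CpG transitions are common in quiet genomes
    return probs / probs.sum()


def _baseline_id() -> np.ndarray:
    probs = np.ones(len(ID83))
    for i, name in enumerate(ID83):
        if name.startswith(("1:Del:T", "1:Ins:T")):
            probs[i] *= 3.0  # T-homopolymer slippage dominates real indels
    return probs / probs.sum()


_CN_CLASS_WEIGHT = {
    "0:HomDel": 0.01,
    "1:LOH": 0.08,
    "2:LOH": 0.06,
    "3-4:LOH": 0.03,
    "5-8:LOH": 0.012,
    "9+:LOH": 0.004,
    "2:HET": 0.40,
    "3-4:HET": 0.28,
    "5-8:HET": 0.10,
    "9+:HET": 0.024,
}
_CN_BIN_WEIGHT = {
    "0-100kb": 0.10,
    "100kb-1Mb": 0.20,
    "1-10Mb": 0.30,
    "10-40Mb": 0.25,
    ">40Mb": 0.15,
    ">1Mb": 0.15,
}


def _baseline_cn() -> np.ndarray:
    probs = np.empty(len(CN48))
    for i, name in enumerate(CN48):
        cls, zyg, size_bin = name.split(":")
        probs[i] = _CN_CLASS_WEIGHT[f"{cls}:{zyg}"] * _CN_BIN_WEIGHT[size_bin]
    return probs / probs.sum()


def _tilt(probs: np.ndarray, names: Sequence[str], boosted: set[str], factor: float) -> np.ndarray:
    tilted = probs.copy()
    for i, name in enumerate(names):
        if name in boosted:
            tilted[i] *= factor
    return tilted / tilted.sum()


def _class_probs(config: SimulationConfig) -> dict[str, dict[str, np.ndarray]]:
    """Tilted channel-probability vectors for each class x label."""
    eff = config.effects
    sbs = _baseline_sbs()
    ids = _baseline_id()
    cn = _baseline_cn()
    nctg = set(feature_channels("n_ct_g"))
    ncgt = set(feature_channels("n_cg_t"))
    del5 = set(feature_channels("del5_mh"))
    loh = set(feature_channels("loh_1_40"))
    het39 = set(feature_channels("het3_9_10_40"))
    het24 = set(feature_channels("het2_4_gt40"))
    return {
        "sbs96": {
            "HRD": _tilt(sbs, SBS96, ncgt, eff.ncgt_hrd),
            "HRP": _tilt(sbs, SBS96, nctg, eff.nctg_hrp),
        },
        "id83": {
            "HRD": _tilt(ids, ID83, del5, eff.del5_mh_hrd),
            "HRP": ids,
        },
        "cn48": {
            "HRD": _tilt(_tilt(cn, CN48, loh, eff.loh_1_40_hrd), CN48, het39, eff.het3_9_10_40_hrd),
            "HRP": _tilt(cn, CN48, het24, eff.het2_4_gt40_hrp),
        },
    }


def _sample_labels(config: SimulationConfig) -> pd.Series:
    n = config.n_hrd + config.n_hrp
    width = max(4, len(str(n)))
    ids = [f"{config.sample_prefix}{i + 1:0{width}d}" for i in range(n)]
    labels = ["HRD"] * config.n_hrd + ["HRP"] * config.n_hrp
    return pd.Series(labels, index=ids, name="label")


def _draw_counts(
    rng: np.random.Generator,
    base: np.ndarray,
    burden: int,
    concentration: float,
) -> np.ndarray:
    jittered = rng.dirichlet(concentration * base)
    return rng.multinomial(burden, jittered)


def simulate_channel_counts(
    config: SimulationConfig,
) -> tuple[list[ChannelCatalog], pd.Series]:
    """Draw per-sample channel catalogs without materializing records.

    This is the fast path used for replicated experiments; statistically it
    is identical to classifying the records emitted by
    :func:`simulate_cohort`.
    """
    rng = np.random.default_rng(config.seed)
    labels = _sample_labels(config)
    probs = _class_probs(config)
    catalogs = []
    for sample_id, label in labels.items():
        cat = ChannelCatalog(sample_id)
        for channel_class, names, burden in (
            ("sbs96", SBS96, config.sbs_burden),
            ("id83", ID83, config.indel_burden),
            ("cn48", CN48, config.n_segments),
        ):
            counts = _draw_counts(
                rng, probs[channel_class][label], burden, config.dirichlet_concentration
            )
            setattr(cat, channel_class, pd.Series(counts, index=list(names)))
        catalogs.append(cat)
    return catalogs, labels


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _random_base_not(rng: np.random.Generator, not_base: str) -> str:
    choices = [b for b in BASES if b != not_base]
    return choices[rng.integers(0, 3)]


def _random_position(rng: np.random.Generator) -> tuple[str, int]:
    chrom = list(TOY_CHROMOSOMES)[rng.integers(0, len(TOY_CHROMOSOMES))]
    return chrom, int(rng.integers(1, TOY_CHROMOSOMES[chrom] - 100))


def _emit_sbs(
    rng: np.random.Generator, sample_id: str, channel: str
) -> MutationRecord:
    c5, ref, alt, c3 = channel[0], channel[2], channel[4], channel[6]
    if rng.random() < 0.5:  # emit the purine-strand representation
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        c5, c3 = COMPLEMENT[c3], COMPLEMENT[c5]
    chrom, pos = _random_position(rng)
    return MutationRecord(sample_id, chrom, pos, ref, alt, c5, c3)


def _flanks_for_copies(
    rng: np.random.Generator, motif: str, copies: int
) -> tuple[str, str]:
    """Flanks containing exactly ``copies`` adjacent whole copies of motif.

    All copies are placed on the 3' side, terminated by a breaker base; the
    5' flank ends in a base differing from the motif's last base, so it
    contributes neither copies nor microhomology.
    """
    breaker3 = _random_base_not(rng, motif[0])
    tail = _random_bases(rng, _FLANK_LEN)
    flank3 = (motif * copies + breaker3 + tail)[:_FLANK_LEN + 5 * len(motif)]
    head = _random_bases(rng, _FLANK_LEN - 1)
    flank5 = head + _random_base_not(rng, motif[-1])
    return flank5, flank3


def _flanks_for_microhomology(
    rng: np.random.Generator, seq: str, mh: int
) -> tuple[str, str]:
    """Flanks giving microhomology ``mh`` (from the 3' side) and no repeat."""
    breaker = _random_base_not(rng, seq[mh])
    flank3 = seq[:mh] + breaker + _random_bases(rng, _FLANK_LEN - mh - 1)
    flank5 = _random_bases(rng, _FLANK_LEN - 1) + _random_base_not(rng, seq[-1])
    return flank5, flank3


def _emit_indel(
    rng: np.random.Generator, sample_id: str, channel: str
) -> IndelRecord:
    size_label, op, context, num = channel.split(":")
    kind = "deletion" if op == "Del" else "insertion"
    number = int(num)
    if context in ("C", "T"):
        seq = context
        copies = number if number < 5 else 5 + int(rng.integers(0, 3))
        flank5, flank3 = _flanks_for_copies(rng, seq, copies)
    elif context == "R":
        length = int(size_label) if size_label != "5" else 5 + int(rng.integers(0, 2))
        seq = _random_bases(rng, length)
        copies = number if number < 5 else 5
        flank5, flank3 = _flanks_for_copies(rng, seq, copies)
        if kind == "deletion" and copies == 0:
            # R:0 deletions additionally require zero microhomology
            flank5, flank3 = _flanks_for_microhomology(rng, seq, 0)
    else:  # microhomology deletion
        length = int(size_label) if number < 5 else 6
        seq = _random_bases(rng, length)
        flank5, flank3 = _flanks_for_microhomology(rng, seq, number)
    if rng.random() < 0.5:  # emit the opposite-strand representation
        seq, flank5, flank3 = (
            reverse_complement(seq),
            reverse_complement(flank3),
            reverse_complement(flank5),
        )
    chrom, pos = _random_position(rng)
    return IndelRecord(sample_id, chrom, pos, kind, seq, flank5, flank3)


_SIZE_RANGES = {
    "0-100kb": (1_000, 100_000),
    "100kb-1Mb": (100_001, 1_000_000),
    "1-10Mb": (1_000_001, 10_000_000),
    "10-40Mb": (10_000_001, 40_000_000),
    ">40Mb": (40_000_001, 55_000_000),
    ">1Mb": (1_000_001, 5_000_000),
}
_TCN_VALUES = {"0": (0,), "1": (1,), "2": (2,), "3-4": (3, 4), "5-8": (5, 6, 7, 8), "9+": (9, 10, 11, 12)}


def _emit_segment(
    rng: np.random.Generator, sample_id: str, channel: str
) -> CNSegment:
    cls, zyg, size_bin = channel.split(":")
    tcn_options = _TCN_VALUES[cls]
    tcn = int(tcn_options[rng.integers(0, len(tcn_options))])
    if zyg == "HomDel":
        major = minor = 0
    elif zyg == "LOH":
        major, minor = tcn, 0
    else:
        minor = int(rng.integers(1, tcn // 2 + 1))
        major = tcn - minor
    lo, hi = _SIZE_RANGES[size_bin]
    size = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    size = min(max(size, lo), hi)
    chrom = list(TOY_CHROMOSOMES)[rng.integers(0, len(TOY_CHROMOSOMES))]
    start = int(rng.integers(0, TOY_CHROMOSOMES[chrom] - size))
    return CNSegment(sample_id, chrom, start, start + size, major, minor)


def _annotations(
    rng: np.random.Generator, labels: pd.Series, cancer_type: str
) -> list[GroundTruthAnnotation]:
    threshold = {"breast": 42, "ovarian": 63}[cancer_type]
    out = []
    for sample_id, label in labels.items():
        if label == "HRD":
            score = int(rng.integers(threshold, threshold + 50))
            brca = bool(rng.random() < 0.3)
        else:
            score = int(rng.integers(0, threshold))
            brca = False
        out.append(
            GroundTruthAnnotation(
                sample_id=sample_id,
                hrd_score=score,
                brca_defect=brca,
                cancer_type=cancer_type,
            )
        )
    return out


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a labeled cohort of concrete records on the toy genome.

    The records round-trip: classifying an emitted record reproduces the
    channel it was drawn from, so ``build_catalogs`` on this cohort matches
    the underlying multinomial draws.
    """
    rng = np.random.default_rng(config.seed)
    labels = _sample_labels(config)
    probs = _class_probs(config)
    mutations: list[MutationRecord] = []
    indels: list[IndelRecord] = []
    segments: list[CNSegment] = []
    for sample_id, label in labels.items():
        sbs_counts = _draw_counts(
            rng, probs["sbs96"][label], config.sbs_burden, config.dirichlet_concentration
        )
        for idx in np.repeat(np.arange(len(SBS96)), sbs_counts):
            mutations.append(_emit_sbs(rng, sample_id, SBS96[idx]))
        id_counts = _draw_counts(
            rng, probs["id83"][label], config.indel_burden, config.dirichlet_concentration
        )
        for idx in np.repeat(np.arange(len(ID83)), id_counts):
            indels.append(_emit_indel(rng, sample_id, ID83[idx]))
        cn_counts = _draw_counts(
            rng, probs["cn48"][label], config.n_segments, config.dirichlet_concentration
        )
        for idx in np.repeat(np.arange(len(CN48)), cn_counts):
            segments.append(_emit_segment(rng, sample_id, CN48[idx]))
    annotations = _annotations(rng, labels, config.cancer_type)
    return SimulatedCohort(
        mutations=mutations,
        indels=indels,
        segments=segments,
        labels=labels,
        annotations=annotations,
        config=config,
    )


def mini_exome_targets(
    fraction: float = 0.01, target_bp: int = 1_000, seed: Optional[int] = None
) -> list[tuple[str, int, int]]:
    """A synthetic exome: evenly spaced targets covering ~``fraction`` of the
    toy genome (BED-style half-open intervals)."""
    spacing = int(target_bp / fraction)
    intervals = []
    for chrom, length in TOY_CHROMOSOMES.items():
        for start in range(spacing // 2, length - target_bp, spacing):
            intervals.append((chrom, start, start + target_bp))
    return intervals
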