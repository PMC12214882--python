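"""Collapse channel catalogs into the six HRD-predictive features.

The six features, in their fixed order:

==============  =====================================================
name            definition
==============  =====================================================
n_ct_g          proportion of SBSs that are C>T at NpCpG (CpG
                transitions) — enriched in HR-proficient tumors
n_cg_t          proportion of SBSs that are C>G at NpCpT — enriched in
                HR-deficient tumors
del5_mh         deletions >= 5 bp with flanking microhomology
                (5:Del:M:1-5); absolute count by default, optionally a
                proportion of all indels
loh_1_40        proportion of CN segments that are LOH of 1-40 Mb
het3_9_10_40    proportion of CN segments that are heterozygous with
                TCN 3-9 and size 10-40 Mb
het2_4_gt40     proportion of CN segments that are heterozygous with
                TCN 2-4 and size > 40 Mb
==============  =====================================================

Ground-truth HRD labels for training follow the genomic-scar convention:
HRD score >= 42 (breast) or >= 63 (ovarian), or any BRCA1/2 defect
(germline, somatic or epigenetic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .catalogs import ChannelCatalog
from .schemas import FEATURE_ORDER, feature_channels

logger = logging.getLogger(__name__)

HRD_SCORE_THRESHOLDS = {"breast": 42, "ovarian": 63}

_CLASS_OF_FEATURE = {
    "n_ct_g": "sbs96",
    "n_cg_t": "sbs96",
    "del5_mh": "id83",
    "loh_1_40": "cn48",
    "het3_9_10_40": "cn48",
    "het2_4_gt40": "cn48",
}


@dataclass(frozen=True)
class FeatureVector:
    """The six engineered features for one sample."""

    sample_id: str
    n_ct_g: float
    n_cg_t: float
    del5_mh: float
    loh_1_40: float
    het3_9_10_40: float
    het2_4_gt40: float
    assay: str  # "WGS" | "WES"
    low_confidence: bool = False

    def as_array(self) -> list[float]:
        return [getattr(self, name) for name in FEATURE_ORDER]


def derive_features(
    catalog: ChannelCatalog,
    assay: str,
    del5mh_as_count: bool = True,
) -> FeatureVector:
    """Compute the six features from one sample's channel catalog.

    Proportions are within-class (SBS counts over total SBS, CN counts over
    total segments). A class with zero events yields zero for its features
    and flags the sample low-confidence.
    """
    if assay not in ("WGS", "WES"):
        raise ValueError(f"unknown assay {assay!r}; expected WGS or WES")
    values: dict[str, float] = {}
    low_confidence = False
    for name in FEATURE_ORDER:
        channel_class = _CLASS_OF_FEATURE[name]
        counts = catalog.counts(channel_class)
        numerator = counts.reindex(feature_channels(name)).sum()
        if name == "del5_mh" and del5mh_as_count:
            values[name] = float(numerator)
            continue
        total = counts.sum()
        if total == 0:
            if not low_confidence:
                logger.warning(
                    "sample %s has no %s events; %s features set to 0 "
                    "(low confidence)",
                    catalog.sample_id,
                    channel_class,
                    channel_class,
                )
            low_confidence = True
            values[name] = 0.0
        else:
            values[name] = float(numerator) / float(total)
    return FeatureVector(
        sample_id=catalog.sample_id,
        assay=assay,
        low_confidence=low_confidence,
        **values,
    )


def features_frame(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    """Samples x features table in the fixed feature order."""
    frame = pd.DataFrame(
        [[v.sample_id, *v.as_array(), v.assay] for v in vectors],
        columns=["sample", *FEATURE_ORDER, "assay"],
    )
    return frame


@dataclass(frozen=True)
class GroundTruthAnnotation:
    """External HRD evidence for one sample used only to assign labels."""

    sample_id: str
    hrd_score: Optional[int] = None
    brca_defect: bool = False
    cancer_type: Optional[str] = None  # "breast" | "ovarian"


def annotate_ground_truth(annotation: GroundTruthAnnotation) -> str:
    """Label a sample HRD or HRP from its scar score and BRCA1/2 status.

    HRD if the genomic-scar HRD score reaches the cancer-type threshold
    (42 breast / 63 ovarian) or the sample carries any BRCA1/2 defect;
    otherwise HRP.
    """
    if annotation.brca_defect:
        return "HRD"
    if annotation.hrd_score is None:
        if annotation.cancer_type is None:
            raise ValueError(
                f"sample {annotation.sample_id}: no HRD evidence at all "
                "(need hrd_score or brca_defect)"
            )
        return "HRP"
    if annotation.cancer_type not in HRD_SCORE_THRESHOLDS:
        raise ValueError(
            f"sample {annotation.sample_id}: cancer_type is required to "
            "interpret an HRD score (got "
            f"{annotation.cancer_type!r})"
        )
    threshold = HRD_SCORE_THRESHOLDS[annotation.cancer_type]
    return "HRD" if annotation.hrd_score >= threshold else "HRP"


def labels_from_annotations(
    annotations: Iterable[GroundTruthAnnotation],
) -> pd.Series:
    labels = {a.sample_id: annotate_ground_truth(a) for a in annotations}
    return pd.Series(labels, name="label")
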