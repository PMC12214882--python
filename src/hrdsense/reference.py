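"""Published reference-cohort metadata for HRD benchmark datasets.

These are the reported class compositions and cross-assay concordance
figures for the public breast-cancer cohorts commonly used to train and
validate HRD classifiers. They are carried as metadata (counts plus the
percentage as reported, at its printed precision) so that consistency of
the reported fractions can be checked arithmetically; none of them enters
any computation on user data.
"""

from __future__ import annotations

#: WGS breast training cohort: 371 samples, 131 HRD / 240 HRP.
WGS_BREAST_TRAINING = {"n_total": 371, "n_hrd": 131, "reported_pct_hrd": 35.0}

#: WES breast training cohort: 672 samples, 156 HRD / 516 HRP.
WES_BREAST_TRAINING = {"n_total": 672, "n_hrd": 156, "reported_pct_hrd": 23.0}

#: WES ovarian training cohort: 182 samples, 82 HRD / 100 HRP (no percentage
#: was reported for this cohort, so only the raw counts are carried).
WES_OVARIAN_TRAINING = {"n_total": 182, "n_hrd": 82}

#: 145 chemotherapy-treated TNBC benchmark: samples annotated differently
#: from WGS vs downsampled-WES input, per tool (count and reported percent).
TNBC_WGS_DWES_DISCORDANCE = {
    "n_total": 145,
    "six_feature_svm": {"n_discordant": 9, "reported_pct": 6.2},
    "signature_based_wgs_tool": {"n_discordant": 39, "reported_pct": 26.9},
}


def pct_hrd(cohort: dict) -> float:
    """HRD percentage recomputed from the cohort's raw counts."""
    return 100.0 * cohort["n_hrd"] / cohort["n_total"]


def pct_discordant(n_discordant: int, n_total: int) -> float:
    return 100.0 * n_discordant / n_total
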