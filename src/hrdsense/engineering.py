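"""Channel-enrichment screening between HRD and HRP cohorts.

This is the feature-engineering diagnostic: for every one of the 96 + 83 + 48
channels, compare its pooled event counts between the two groups with a
two-sided Fisher exact test, quote the effect as the log2 fold change of the
group-mean channel proportions, adjust all p-values jointly with
Benjamini-Hochberg, and select channels on a volcano-style rule
(|log2FC| above an assay-specific threshold and -log10(FDR) > 3).

The count-level 2x2 table for a channel is

    [[events in channel (HRD), other events of the class (HRD)],
     [events in channel (HRP), other events of the class (HRP)]]

while the fold change is computed on mean per-sample proportions, matching
the axes of a volcano plot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalogs import ChannelCatalog

#: |log2FC| selection thresholds by assay; the FDR rule is -log10(q) > 3.
LOG2FC_THRESHOLDS = {"WGS": 0.75, "WES": 0.25}
NEG_LOG10_FDR_THRESHOLD = 3.0

CHANNEL_CLASSES = ("sbs96", "id83", "cn48")


@dataclass(frozen=True)
class EnrichmentResult:
    channel: str
    channel_class: str
    mean_prop_hrd: float
    mean_prop_hrp: float
    log2_fc: float
    p_value: float
    q_value: float
    selected: bool
    direction: str  # "HRD" | "HRP"


def _split_groups(
    catalogs: Sequence[ChannelCatalog], labels: Mapping[str, str]
) -> tuple[list[ChannelCatalog], list[ChannelCatalog]]:
    hrd = [c for c in catalogs if labels[c.sample_id] == "HRD"]
    hrp = [c for c in catalogs if labels[c.sample_id] == "HRP"]
    if not hrd or not hrp:
        raise ValueError("both HRD and HRP groups must be non-empty")
    return hrd, hrp


def group_mean_profiles(
    catalogs: Sequence[ChannelCatalog], labels: Mapping[str, str]
) -> dict[str, pd.DataFrame]:
    """Mean per-sample channel proportions within each group.

    Returns one frame per channel class with columns ``HRD`` and ``HRP``.
    """
    hrd, hrp = _split_groups(catalogs, labels)
    out = {}
    for channel_class in CHANNEL_CLASSES:
        mean_hrd = pd.concat(
            [c.proportions(channel_class) for c in hrd], axis=1
        ).mean(axis=1)
        mean_hrp = pd.concat(
            [c.proportions(channel_class) for c in hrp], axis=1
        ).mean(axis=1)
        frame = pd.DataFrame({"HRD": mean_hrd, "HRP": mean_hrp})
        frame.index.name = "channel"
        out[channel_class] = frame
    return out


def fisher_channel_test(k_hrd: int, n_hrd: int, k_hrp: int, n_hrp: int) -> float:
    """Two-sided Fisher exact p for one channel's pooled 2x2 table."""
    table = [[k_hrd, n_hrd - k_hrd], [k_hrp, n_hrp - k_hrp]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def _log2_fold_changes(means: pd.DataFrame, epsilon: float | None) -> pd.Series:
    """log2(mean HRD / mean HRP) with a pseudo-proportion guard for zeros.

    The default epsilon is half the smallest nonzero mean proportion observed
    in the class (either group); if every mean is zero the fold change is 0.
    """
    values = means.to_numpy(dtype=float)
    nonzero = values[values > 0]
    if epsilon is None:
        epsilon = float(nonzero.min()) / 2.0 if nonzero.size else 1.0
    hrd = np.maximum(means["HRD"].to_numpy(dtype=float), epsilon)
    hrp = np.maximum(means["HRP"].to_numpy(dtype=float), epsilon)
    fc = np.log2(hrd / hrp)
    both_zero = (means["HRD"] == 0) & (means["HRP"] == 0)
    fc[both_zero.to_numpy()] = 0.0
    return pd.Series(fc, index=means.index)


def channel_enrichment(
    catalogs: Sequence[ChannelCatalog],
    labels: Mapping[str, str],
    epsilon: float | None = None,
    joint_fdr: bool = True,
) -> list[EnrichmentResult]:
    """Per-channel HRD-vs-HRP enrichment over all three channel classes.

    ``joint_fdr`` adjusts all 227 channels as one BH family (default); when
    False, each channel class is adjusted separately.
    """
    hrd, hrp = _split_groups(catalogs, labels)
    means = group_mean_profiles(catalogs, labels)

    rows: list[dict] = []
    for channel_class in CHANNEL_CLASSES:
        counts_hrd = sum(c.counts(channel_class) for c in hrd)
        counts_hrp = sum(c.counts(channel_class) for c in hrp)
        n_hrd = int(counts_hrd.sum())
        n_hrp = int(counts_hrp.sum())
        fold = _log2_fold_changes(means[channel_class], epsilon)
        for channel in counts_hrd.index:
            k_hrd = int(counts_hrd[channel])
            k_hrp = int(counts_hrp[channel])
            if k_hrd == 0 and k_hrp == 0:
                p = 1.0
            else:
                p = fisher_channel_test(k_hrd, n_hrd, k_hrp, n_hrp)
            rows.append(
                {
                    "channel": channel,
                    "channel_class": channel_class,
                    "mean_prop_hrd": float(means[channel_class].loc[channel, "HRD"]),
                    "mean_prop_hrp": float(means[channel_class].loc[channel, "HRP"]),
                    "log2_fc": float(fold[channel]),
                    "p_value": p,
                }
            )

    frame = pd.DataFrame(rows)
    if joint_fdr:
        frame["q_value"] = multipletests(frame["p_value"], method="fdr_bh")[1]
    else:
        frame["q_value"] = np.nan
        for channel_class in CHANNEL_CLASSES:
            mask = frame["channel_class"] == channel_class
            frame.loc[mask, "q_value"] = multipletests(
                frame.loc[mask, "p_value"], method="fdr_bh"
            )[1]

    return [
        EnrichmentResult(
            channel=row.channel,
            channel_class=row.channel_class,
            mean_prop_hrd=row.mean_prop_hrd,
            mean_prop_hrp=row.mean_prop_hrp,
            log2_fc=row.log2_fc,
            p_value=row.p_value,
            q_value=float(row.q_value),
            selected=False,
            direction="HRD" if row.log2_fc > 0 else "HRP",
        )
        for row in frame.itertuples()
    ]


def select_channels(
    results: Sequence[EnrichmentResult], assay: str
) -> dict[str, set[str]]:
    """Volcano selection: |log2FC| > threshold(assay) and -log10(q) > 3."""
    if assay not in LOG2FC_THRESHOLDS:
        raise ValueError(f"unknown assay {assay!r}; expected WGS or WES")
    fc_threshold = LOG2FC_THRESHOLDS[assay]
    hrd_enriched: set[str] = set()
    hrp_enriched: set[str] = set()
    for res in results:
        if abs(res.log2_fc) <= fc_threshold:
            continue
        # -log10(q) > 3, written q < 1e-3 so q = 0 needs no special-casing
        if not res.q_value < 10.0 ** (-NEG_LOG10_FDR_THRESHOLD):
            continue
        (hrd_enriched if res.log2_fc > 0 else hrp_enriched).add(res.channel)
    return {"hrd_enriched": hrd_enriched, "hrp_enriched": hrp_enriched}


def mark_selected(
    results: Sequence[EnrichmentResult], assay: str
) -> list[EnrichmentResult]:
    """Copies of ``results`` with ``selected`` filled per the assay rule."""
    from dataclasses import replace

    chosen = select_channels(results, assay)
    picked = chosen["hrd_enriched"] | chosen["hrp_enriched"]
    return [replace(r, selected=r.channel in picked) for r in results]


def intersect_assays(
    wgs_selection: Mapping[str, set[str]], wes_selection: Mapping[str, set[str]]
) -> dict[str, set[str]]:
    """Consensus channels significant in both the WGS and WES screens."""
    return {
        key: set(wgs_selection[key]) & set(wes_selection[key])
        for key in ("hrd_enriched", "hrp_enriched")
    }


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
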