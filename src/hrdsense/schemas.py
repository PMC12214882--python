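"""Canonical mutational-channel schemas.

Three fixed channel vocabularies are used throughout the package:

* **SBS-96** — single-base substitutions in their pyrimidine-centric
  trinucleotide context, e.g. ``A[C>T]G``.
* **ID-83** — small insertions/deletions stratified by event type, length,
  flanking repeat-unit count and microhomology length, e.g. ``5:Del:M:3``.
* **CN-48** — allele-specific copy-number segments stratified by total copy
  number (TCN) class, zygosity and segment-size bin, e.g. ``2:LOH:10-40Mb``.

The channel *orderings* defined here are the package's canonical output
ordering for catalog files and are stable across versions.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _sbs96_names() -> list[str]:
    return [
        f"{five}[{sub}]{three}"
        for sub in SUBSTITUTIONS
        for five in BASES
        for three in BASES
    ]


def _id83_names() -> list[str]:
    names: list[str] = []
    for base in ("C", "T"):
        names += [f"1:Del:{base}:{n}" for n in range(6)]
    for base in ("C", "T"):
        names += [f"1:Ins:{base}:{n}" for n in range(6)]
    for length in (2, 3, 4, 5):
        names += [f"{length}:Del:R:{n}" for n in range(6)]
    for length in (2, 3, 4, 5):
        names += [f"{length}:Ins:R:{n}" for n in range(6)]
    for length, max_mh in ((2, 1), (3, 2), (4, 3), (5, 5)):
        names += [f"{length}:Del:M:{m}" for m in range(1, max_mh + 1)]
    return names


# TCN classes for LOH segments (TCN >= 1) and heterozygous segments (TCN >= 2).
TCN_CLASSES_LOH = ("1", "2", "3-4", "5-8", "9+")
TCN_CLASSES_HET = ("2", "3-4", "5-8", "9+")
SIZE_BINS = ("0-100kb", "100kb-1Mb", "1-10Mb", "10-40Mb", ">40Mb")
SIZE_BINS_HOMDEL = ("0-100kb", "100kb-1Mb", ">1Mb")


def _cn48_names() -> list[str]:
    names = [f"0:HomDel:{b}" for b in SIZE_BINS_HOMDEL]
    names += [f"{t}:LOH:{b}" for t in TCN_CLASSES_LOH for b in SIZE_BINS]
    names += [f"{t}:HET:{b}" for t in TCN_CLASSES_HET for b in SIZE_BINS]
    return names


SBS96 = tuple(_sbs96_names())
ID83 = tuple(_id83_names())
CN48 = tuple(_cn48_names())

assert len(SBS96) == 96 and len(set(SBS96)) == 96
assert len(ID83) == 83 and len(set(ID83)) == 83
assert len(CN48) == 48 and len(set(CN48)) == 48

CHANNEL_CLASSES = {"sbs96": SBS96, "id83": ID83, "cn48": CN48}

#: Fixed feature order; the trained-model contract depends on it.
FEATURE_ORDER = (
    "n_ct_g",
    "n_cg_t",
    "del5_mh",
    "loh_1_40",
    "het3_9_10_40",
    "het2_4_gt40",
)


@lru_cache(maxsize=1)
def feature_channel_map() -> pd.DataFrame:
    """Load the shipped channel-to-feature membership table.

    Returns a frame with columns ``feature``, ``channel_class``, ``channel``.
    Each channel appears under at most one feature (the map is a partial
    function from channels to features).
    """
    with resources.files("hrdsense.data").joinpath(
        "feature_channel_map.tsv"
    ).open() as fh:
        table = pd.read_csv(fh, sep="\t", comment="#")
    return table


def feature_channels(feature: str) -> tuple[str, ...]:
    """Channels contributing to one of the six features, in canonical order."""
    table = feature_channel_map()
    if feature not in FEATURE_ORDER:
        raise KeyError(f"unknown feature {feature!r}")
    return tuple(table.loc[table["feature"] == feature, "channel"])


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))
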