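"""Independent reference implementations used only to check the package.

Each oracle re-derives its quantity by direct brute force or enumeration,
without calling the code path it validates.
"""

from __future__ import annotations

import math


def oracle_sbs_channel(ref: str, alt: str, c5: str, c3: str) -> str:
    """SBS-96 name by explicit lookup over the strand-collapsed alphabet."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if ref in ("A", "G"):
        ref, alt, c5, c3 = comp[ref], comp[alt], comp[c3], comp[c5]
    return f"{c5}[{ref}>{alt}]{c3}"


def _copies_right(motif: str, flank: str) -> int:
    n = 0
    rest = flank
    while rest.startswith(motif):
        n += 1
        rest = rest[len(motif):]
    return n


def _copies_left(motif: str, flank: str) -> int:
    n = 0
    rest = flank
    while rest.endswith(motif):
        n += 1
        rest = rest[: len(rest) - len(motif)]
    return n


def _longest_prefix_match(seq: str, flank: str, limit: int) -> int:
    best = 0
    for length in range(1, limit + 1):
        if flank[:length] == seq[:length]:
            best = length
    return best


def _longest_suffix_match(seq: str, flank: str, limit: int) -> int:
    best = 0
    for length in range(1, limit + 1):
        if flank[-length:] == seq[-length:]:
            best = length
    return best


def oracle_indel_channel(kind: str, seq: str, flank5: str, flank3: str) -> str:
    """ID-83 name by direct application of the repeat/microhomology rules."""
    length = len(seq)
    copies = min(_copies_right(seq, flank3) + _copies_left(seq, flank5), 5)
    if length == 1:
        base = {"A": "T", "G": "C", "C": "C", "T": "T"}[seq]
        op = "Del" if kind == "deletion" else "Ins"
        return f"1:{op}:{base}:{copies}"
    size = min(length, 5)
    if kind == "insertion":
        return f"{size}:Ins:R:{copies}"
    if copies >= 1:
        return f"{size}:Del:R:{copies}"
    limit = min(length - 1, 5)
    mh = max(
        _longest_prefix_match(seq, flank3, min(limit, len(flank3))),
        _longest_suffix_match(seq, flank5, min(limit, len(flank5))),
    )
    if mh >= 1:
        return f"{size}:Del:M:{min(mh, 5)}"
    return f"{size}:Del:R:0"


def oracle_cn_channel(major: int, minor: int, size: int) -> str:
    """CN-48 name from the tabulated TCN x zygosity x size-bin layout."""
    tcn = major + minor
    if tcn == 0:
        if size <= 100_000:
            return "0:HomDel:0-100kb"
        if size <= 1_000_000:
            return "0:HomDel:100kb-1Mb"
        return "0:HomDel:>1Mb"
    if tcn == 1:
        cls = "1"
    elif tcn == 2:
        cls = "2"
    elif tcn in (3, 4):
        cls = "3-4"
    elif 5 <= tcn <= 8:
        cls = "5-8"
    else:
        cls = "9+"
    zyg = "LOH" if minor == 0 else "HET"
    if size <= 100_000:
        size_bin = "0-100kb"
    elif size <= 1_000_000:
        size_bin = "100kb-1Mb"
    elif size <= 10_000_000:
        size_bin = "1-10Mb"
    elif size <= 40_000_000:
        size_bin = "10-40Mb"
    else:
        size_bin = ">40Mb"
    return f"{cls}:{zyg}:{size_bin}"


def oracle_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's (with the standard
    1 + 1e-7 relative slack for floating-point ties).
    """
    n1, n2 = a + b, c + d
    K, N = a + c, a + b + c + d
    denom = math.comb(N, n1)
    lo, hi = max(0, K - n2), min(K, n1)
    pmf = {
        k: math.comb(K, k) * math.comb(N - K, n1 - k) / denom
        for k in range(lo, hi + 1)
    }
    p_obs = pmf[a]
    return min(1.0, sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7)))


def oracle_auc(probabilities, truth) -> float:
    """AUC as the brute-force pairwise concordance over all (pos, neg) pairs."""
    pos = [p for p, t in zip(probabilities, truth) if t == 1]
    neg = [p for p, t in zip(probabilities, truth) if t == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def random_indel(rng, adversarial: bool = True):
    """One randomized indel (kind, seq, flank5, flank3) for oracle checks.

    Half of the draws embed whole and partial copies of the event sequence
    in the flanks so repeat and microhomology branches are exercised.
    """
    bases = "ACGT"

    def rand(n):
        return "".join(bases[i] for i in rng.integers(0, 4, size=n))

    kind = "deletion" if rng.random() < 0.6 else "insertion"
    length = int(rng.integers(1, 9))
    seq = rand(length)
    flank5, flank3 = rand(30), rand(30)
    if adversarial and rng.random() < 0.5:
        # keep the random tail/head intact so a scan always terminates at a
        # mismatch instead of running off the end of the flank
        k = int(rng.integers(0, 4))
        partial = seq[: rng.integers(0, length + 1)]
        flank3 = seq * k + partial + rand(30)
        if rng.random() < 0.5:
            k5 = int(rng.integers(0, 3))
            partial5 = seq[int(rng.integers(0, length)):]
            flank5 = rand(30) + partial5 + seq * k5
    return kind, seq, flank5, flank3
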