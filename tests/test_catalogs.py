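"""Channel classifiers: SBS-96 strand collapse, ID-83 repeat/microhomology
rules, CN-48 zygosity/size binning, and catalog aggregation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrdsense.catalogs import (
    build_catalogs,
    classify_cn_segment,
    classify_indel,
    classify_sbs,
)
from hrdsense.records import (
    ClassificationError,
    CNSegment,
    IndelRecord,
    MutationRecord,
)
from hrdsense.schemas import CN48, COMPLEMENT, ID83, SBS96, reverse_complement

from oracles import oracle_cn_channel, oracle_indel_channel, random_indel


def _snv(ref, alt, c5, c3):
    return MutationRecord("s1", "1", 1000, ref, alt, c5, c3)


def _indel(kind, seq, flank5, flank3):
    return IndelRecord("s1", "1", 1000, kind, seq, flank5, flank3)


class TestSBS96:
    @pytest.mark.parametrize(
        "ref,alt,c5,c3,expected",
        [
            ("C", "T", "A", "G", "A[C>T]G"),
            ("G", "A", "C", "T", "A[C>T]G"),  # purine strand collapses
            ("T", "G", "T", "T", "T[T>G]T"),
            ("A", "C", "A", "A", "T[T>G]T"),
        ],
    )
    def test_examples(self, ref, alt, c5, c3, expected):
        assert classify_sbs(_snv(ref, alt, c5, c3)) == expected

    def test_strand_symmetry_exhaustive(self):
        """All 192 raw contexts collapse pairwise onto the 96 channels."""
        seen = set()
        for ref in "CT":
            for alt in "ACGT":
                if alt == ref:
                    continue
                for c5, c3 in itertools.product("ACGT", repeat=2):
                    forward = classify_sbs(_snv(ref, alt, c5, c3))
                    flipped = classify_sbs(
                        _snv(
                            COMPLEMENT[ref],
                            COMPLEMENT[alt],
                            COMPLEMENT[c3],
                            COMPLEMENT[c5],
                        )
                    )
                    assert forward == flipped
                    seen.add(forward)
        assert seen == set(SBS96)

    def test_invalid_base_raises(self):
        with pytest.raises(ClassificationError):
            _snv("N", "T", "A", "G")


class TestID83:
    @pytest.mark.parametrize(
        "kind,seq,flank5,flank3,expected",
        [
            # T deletion in front of >=5 further Ts: 5+ homopolymer bucket
            ("deletion", "T", "G" * 25, "TTTTTA" + "G" * 20, "1:Del:T:5"),
            # 5 bp deletion, 3 bp of prefix microhomology in the 3' flank
            ("deletion", "ACGTA", "G" * 24 + "C", "ACGC" + "G" * 22, "5:Del:M:3"),
            # C insertion with no adjacent C run
            ("insertion", "C", "A" * 25, "GG" + "A" * 24, "1:Ins:C:0"),
            ("deletion", "A", "G" * 25, "AAAG" + "C" * 22, "1:Del:T:3"),
            ("deletion", "TA", "C" * 25, "TATAG" + "C" * 21, "2:Del:R:2"),
            ("insertion", "ACG", "C" * 25, "ACGACGT" + "C" * 19, "3:Ins:R:2"),
            # microhomology from the 5' side (suffix match)
            ("deletion", "CCGAT", "G" * 22 + "GAT", "CGGG" + "A" * 22, "5:Del:M:3"),
            # whole adjacent copy wins over microhomology
            ("deletion", "ACGTT", "G" * 25, "ACGTTACA" + "G" * 18, "5:Del:R:1"),
            ("deletion", "GC", "A" * 25, "TT" + "A" * 24, "2:Del:R:0"),
        ],
    )
    def test_examples(self, kind, seq, flank5, flank3, expected):
        assert classify_indel(_indel(kind, seq, flank5, flank3)) == expected

    def test_agrees_with_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(3000):
            kind, seq, flank5, flank3 = random_indel(rng)
            expected = oracle_indel_channel(kind, seq, flank5, flank3)
            assert classify_indel(_indel(kind, seq, flank5, flank3)) == expected
            assert expected in ID83

    def test_strand_symmetric(self):
        rng = np.random.default_rng(43)
        for _ in range(500):
            kind, seq, flank5, flank3 = random_indel(rng)
            same = classify_indel(_indel(kind, seq, flank5, flank3))
            flipped = classify_indel(
                _indel(
                    kind,
                    reverse_complement(seq),
                    reverse_complement(flank3),
                    reverse_complement(flank5),
                )
            )
            assert same == flipped

    def test_short_flank_raises(self):
        with pytest.raises(ClassificationError):
            classify_indel(_indel("deletion", "ACGTA", "G", "A"))

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(
        kind=st.sampled_from(["deletion", "insertion"]),
        seq=st.text(alphabet="ACGT", min_size=1, max_size=8),
        flank5=st.text(alphabet="ACGT", min_size=25, max_size=40),
        flank3=st.text(alphabet="ACGT", min_size=25, max_size=40),
    )
    def test_total_and_strand_symmetric_property(self, kind, seq, flank5, flank3):
        """Any indel either maps to a valid ID-83 name or raises an
        ambiguous-flank error, identically on both strands."""
        rc = reverse_complement
        try:
            name = classify_indel(_indel(kind, seq, flank5, flank3))
        except ClassificationError:
            with pytest.raises(ClassificationError):
                classify_indel(_indel(kind, rc(seq), rc(flank3), rc(flank5)))
            return
        assert name in ID83
        assert classify_indel(_indel(kind, rc(seq), rc(flank3), rc(flank5))) == name


class TestCN48:
    @pytest.mark.parametrize(
        "major,minor,size,expected",
        [
            (2, 0, 20_000_000, "2:LOH:10-40Mb"),
            (1, 1, 50_000_000, "2:HET:>40Mb"),
            (2, 2, 60_000_000, "3-4:HET:>40Mb"),
            (0, 0, 50_000, "0:HomDel:0-100kb"),
            (0, 0, 5_000_000, "0:HomDel:>1Mb"),
            (1, 0, 100_000, "1:LOH:0-100kb"),  # right-closed bin edge
            (1, 0, 100_001, "1:LOH:100kb-1Mb"),
            (5, 4, 40_000_000, "9+:HET:10-40Mb"),  # exactly 40 Mb stays 10-40
        ],
    )
    def test_examples(self, major, minor, size, expected):
        seg = CNSegment("s1", "1", 0, size, major, minor)
        assert classify_cn_segment(seg) == expected

    def test_total_and_matches_tabulated_oracle(self):
        """Every (major, minor, size) combination maps onto exactly one of
        the 48 names, matching the hand-tabulated schema."""
        sizes = [
            1, 50_000, 100_000, 100_001, 999_999, 1_000_000, 1_000_001,
            10_000_000, 10_000_001, 40_000_000, 40_000_001, 90_000_000,
        ]
        seen = set()
        for major in range(13):
            for minor in range(major + 1):
                for size in sizes:
                    seg = CNSegment("s", "1", 0, size, major, minor)
                    name = classify_cn_segment(seg)
                    assert name == oracle_cn_channel(major, minor, size)
                    assert name in CN48
                    seen.add(name)
        assert seen == set(CN48)

    def test_invalid_segments_raise(self):
        with pytest.raises(ClassificationError):
            CNSegment("s", "1", 0, 100, -1, 0)
        with pytest.raises(ClassificationError):
            CNSegment("s", "1", 0, 100, 1, 2)  # major < minor
        with pytest.raises(ClassificationError):
            CNSegment("s", "1", 100, 100, 1, 1)  # empty


class TestBuildCatalogs:
    def test_single_sample_counts(self):
        muts = [_snv("C", "T", "A", "G")] * 3
        cats = build_catalogs(mutations=muts)
        assert len(cats) == 1
        assert cats[0].sbs96["A[C>T]G"] == 3
        assert cats[0].sbs96.sum() == 3
        assert cats[0].id83.sum() == 0 and cats[0].cn48.sum() == 0

    def test_empty_input(self):
        assert build_catalogs() == []

    def test_totals_conserved_and_samples_unique(self, record_cohort):
        cats = build_catalogs(
            record_cohort.mutations, record_cohort.indels, record_cohort.segments
        )
        ids = [c.sample_id for c in cats]
        assert ids == sorted(set(ids))
        cfg = record_cohort.config
        for cat in cats:
            assert cat.sbs96.sum() == cfg.sbs_burden
            assert cat.id83.sum() == cfg.indel_burden
            assert cat.cn48.sum() == cfg.n_segments

    def test_mitochondrial_records_dropped(self):
        muts = [
            MutationRecord("s1", "chrM", 5, "C", "T", "A", "G"),
            MutationRecord("s1", "1", 5, "C", "T", "A", "G"),
        ]
        cats = build_catalogs(mutations=muts)
        assert cats[0].sbs96.sum() == 1
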