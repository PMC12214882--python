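"""Classify individual somatic events into their mutational channels.

Shows the three channel systems on hand-built records: a CpG transition
(strand-collapsed), a microhomology-flanked deletion, and an LOH segment.
"""

from hrdsense.catalogs import classify_cn_segment, classify_indel, classify_sbs
from hrdsense.records import CNSegment, IndelRecord, MutationRecord

# C>T at an ApCpG site, reported on the purine strand: G>A with the
# complementary context. Strand collapse maps it to the pyrimidine name.
snv = MutationRecord("sample1", "17", 41_244_000, "G", "A", "C", "T")
print("SBS-96:", classify_sbs(snv))  # -> A[C>T]G

# 5 bp deletion whose first three bases recur at the start of the 3' flank:
# 3 bp of microhomology, the scar of microhomology-mediated end joining.
deletion = IndelRecord(
    "sample1", "13", 32_900_000, "deletion", "ACGTA",
    flank5="G" * 25, flank3="ACGC" + "G" * 22,
)
print("ID-83:", classify_indel(deletion))  # -> 5:Del:M:3

# 20 Mb segment with one retained and one lost allele: mid-sized LOH,
# the copy-number hallmark of HR deficiency.
segment = CNSegment("sample1", "13", 10_000_000, 30_000_000, major_cn=2, minor_cn=0)
print("CN-48:", classify_cn_segment(segment))  # -> 2:LOH:10-40Mb
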