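"""The mate-aware candidate filter on the canonical worked example.

Anchors a0 and a1 are mates.  Candidate sets C(a0) = {r0, r5, r11} and
C(a1) = {r4, r8, r14}; reads r4 and r5 form a read pair (reads 2i and 2i+1
are mates), so each appears in the candidate set of the other anchor's mate
— strong evidence both fragments come from the same locus.  They pass the
filter unconditionally; every other candidate needs mismatch ratio below
t_paired = 0.06.
"""

from msacorrect import EncodedRead, FilterParams, filter_paired
from msacorrect.align import AlignmentResult, Candidate


def cand(read_id, mismatches, overlap=100):
    read = EncodedRead.from_sequence("A" * overlap, read_id=read_id)
    return Candidate(read, AlignmentResult(0, overlap, mismatches, "fwd", True))


c_a0 = [cand(0, 5), cand(5, 30), cand(11, 7)]
c_a1 = [cand(4, 30), cand(8, 5), cand(14, 6)]

f0, f1 = filter_paired(c_a0, c_a1, FilterParams(t_paired=0.06))
print("kept for a0:", sorted(c.read.read_id for c in f0))
print("kept for a1:", sorted(c.read.read_id for c in f1))
print("r5 and r4 survive despite 30% mismatches (mate pair); "
      "r11 (7%) and r14 (6%) fall to the ratio test")
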