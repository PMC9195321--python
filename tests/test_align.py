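"""Shifted-Hamming-distance alignment vs a naive oracle; candidate filters."""

import math

import numpy as np
import pytest

from msacorrect.align import (
    AlignmentResult,
    Candidate,
    FilterParams,
    align_shd,
    filter_paired,
    filter_single,
)
from msacorrect.io_encodings import EncodedRead

COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s):
    return s.translate(COMP)[::-1]


def naive_best_alignment(anchor: str, cand: str, min_overlap_ratio: float):
    """O(n*m) oracle: try every shift and orientation, count mismatches."""
    n = len(anchor)
    floor = max(1, math.ceil(min_overlap_ratio * n))
    best = None
    for orientation, c in (("fwd", cand), ("rc", revcomp(cand))):
        m = len(c)
        for shift in range(-m + 1, n):
            overlap = mism = 0
            for j in range(m):
                i = shift + j
                if 0 <= i < n and anchor[i] != "N" and c[j] != "N":
                    overlap += 1
                    if anchor[i] != c[j]:
                        mism += 1
            if overlap < floor:
                continue
            key = (mism / overlap, abs(shift), 0 if orientation == "fwd" else 1)
            if best is None or key < best[0]:
                best = (key, shift, overlap, mism, orientation)
    if best is None:
        return AlignmentResult(0, 0, 0, "fwd", False)
    _, shift, overlap, mism, orientation = best
    return AlignmentResult(shift, overlap, mism, orientation, True)


def _aln(anchor, cand, mor=0.3):
    return align_shd(
        EncodedRead.from_sequence(anchor), EncodedRead.from_sequence(cand), mor
    )


class TestAlignShd:
    def test_identity(self):
        a = _aln("AAAA", "AAAA")
        assert (a.shift, a.overlap, a.mismatches, a.valid) == (0, 4, 0, True)

    def test_shifted_exact_overlap(self):
        a = _aln("AAAATTTT", "TTTTGGGG", 0.3)
        assert (a.shift, a.overlap, a.mismatches) == (4, 4, 0)
        assert a.orientation == "fwd"

    def test_single_substitution(self):
        a = _aln("ACGT", "ACGA")
        assert (a.shift, a.overlap, a.mismatches) == (0, 4, 1)

    def test_reverse_complement_candidate(self):
        a = _aln("ACGTACGTAA", revcomp("ACGTACGTAA"))
        assert (a.shift, a.mismatches, a.orientation) == (0, 0, "rc")

    def test_n_positions_are_neutral(self):
        a = _aln("ACGTACGT", "ACNTACGT")
        assert a.mismatches == 0
        assert a.overlap == 7  # the N column drops out of the overlap

    def test_no_sufficient_overlap_invalid(self):
        a = _aln("AAAAAAAAAA", "GGGG", mor=0.9)
        assert not a.valid

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_oracle_random(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            n, m = rng.integers(20, 80, size=2)
            anchor = "".join(rng.choice(list("ACGT"), size=n))
            cand = "".join(rng.choice(list("ACGT"), size=m))
            got = _aln(anchor, cand)
            exp = naive_best_alignment(anchor, cand, 0.3)
            assert (got.shift, got.overlap, got.mismatches, got.orientation, got.valid) == (
                exp.shift, exp.overlap, exp.mismatches, exp.orientation, exp.valid
            )

    def test_mismatch_symmetry_per_shift(self):
        """mismatches(a, b at shift s) == mismatches(b, a at shift -s)."""

        def count(a, b, shift):
            return sum(
                a[shift + j] != b[j]
                for j in range(len(b))
                if 0 <= shift + j < len(a)
            )

        rng = np.random.default_rng(99)
        a = "".join(rng.choice(list("ACGT"), size=40))
        b = "".join(rng.choice(list("ACGT"), size=40))
        for s in range(-39, 40):
            assert count(a, b, s) == count(b, a, -s)
        # and the best achievable ratio is direction-independent
        assert _aln(a, b).mismatch_ratio == pytest.approx(_aln(b, a).mismatch_ratio)


def _cand(read_id, overlap, mismatches):
    read = EncodedRead.from_sequence("ACGT", read_id=read_id)
    return Candidate(read, AlignmentResult(0, overlap, mismatches, "fwd", True))


class TestFilters:
    def test_single_keeps_at_threshold(self):
        params = FilterParams(max_mismatch_ratio=0.06)
        kept = filter_single([_cand(0, 50, 2)], params)  # 0.04 <= 0.06
        assert len(kept) == 1

    def test_single_removes_above_threshold(self):
        params = FilterParams(max_mismatch_ratio=0.06)
        assert filter_single([_cand(0, 50, 4)], params) == []  # 0.08 > 0.06

    def test_single_boundary_is_inclusive(self):
        params = FilterParams(max_mismatch_ratio=0.06)
        assert len(filter_single([_cand(0, 50, 3)], params)) == 1  # exactly 0.06

    def test_invalid_alignment_always_removed(self):
        bad = Candidate(
            EncodedRead.from_sequence("ACGT", read_id=0),
            AlignmentResult(0, 0, 0, "fwd", False),
        )
        assert filter_single([bad], FilterParams()) == []

    def test_paired_worked_example(self):
        # anchors a0, a1; candidate sets {r0, r5, r11} and {r4, r8, r14};
        # r4 and r5 are mates (pair 2) so both pass unconditionally even with
        # terrible alignments; the rest pass iff ratio < t_paired = 0.06
        c_a0 = [_cand(0, 100, 5), _cand(5, 100, 30), _cand(11, 100, 7)]
        c_a1 = [_cand(4, 100, 30), _cand(8, 100, 5), _cand(14, 100, 6)]
        f0, f1 = filter_paired(c_a0, c_a1, FilterParams(t_paired=0.06))
        assert {c.read.read_id for c in f0} == {0, 5}  # r11: 0.07 >= 0.06
        assert {c.read.read_id for c in f1} == {4, 8}  # r14: 0.06 not < 0.06

    def test_paired_strictly_less_than(self):
        f0, f1 = filter_paired([_cand(0, 100, 6)], [], FilterParams(t_paired=0.06))
        assert f0 == [] and f1 == []
        f0, _ = filter_paired([_cand(0, 100, 5)], [], FilterParams(t_paired=0.06))
        assert len(f0) == 1  # 0.05 < 0.06

    def test_paired_outputs_are_subsets(self):
        c_a0 = [_cand(i, 100, i) for i in range(0, 20, 2)]
        c_a1 = [_cand(i, 100, i) for i in range(1, 21, 2)]
        f0, f1 = filter_paired(c_a0, c_a1, FilterParams())
        assert {c.read.read_id for c in f0} <= {c.read.read_id for c in c_a0}
        assert {c.read.read_id for c in f1} <= {c.read.read_id for c in c_a1}
        # every mutually-paired candidate is retained
        ids0 = {c.read.read_id for c in c_a0}
        ids1 = {c.read.read_id for c in c_a1}
        mutual0 = {i for i in ids0 if (i ^ 1) in ids1}
        assert mutual0 <= {c.read.read_id for c in f0}

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            FilterParams(t_paired=0.0)
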