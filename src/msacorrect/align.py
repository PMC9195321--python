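"""Gapless semi-global alignment (shifted Hamming distance) and candidate filters.

Illumina errors are almost exclusively substitutions, so candidates are
aligned to the anchor without inner gaps: every shift of the candidate
against the anchor is scored by its mismatch count within the overlap, in
both orientations, and the (orientation, shift) with the smallest
mismatch/overlap ratio wins. N positions are evidence-free and are excluded
from both the overlap and the mismatch count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io_encodings import EncodedRead, reverse_complement

__all__ = [
    "AlignmentResult",
    "FilterParams",
    "Candidate",
    "align_shd",
    "filter_single",
    "filter_paired",
]

_PAD = 5  # outside-anchor sentinel: never matches, never counts as overlap


@dataclass(frozen=True)
class AlignmentResult:
    """Best gapless placement of a candidate against an anchor.

    ``shift`` is the offset of the candidate's first base in anchor
    coordinates (negative: candidate starts left of the anchor). ``overlap``
    counts the positions compared (N positions excluded), ``mismatches`` the
    disagreements among them. ``orientation`` is ``"fwd"`` or ``"rc"``; for
    ``"rc"`` the shift refers to the reverse-complemented candidate.
    """

    shift: int
    overlap: int
    mismatches: int
    orientation: str
    valid: bool

    @property
    def mismatch_ratio(self) -> float:
        return self.mismatches / self.overlap if self.overlap else math.inf


@dataclass(frozen=True)
class FilterParams:
    max_mismatch_ratio: float = 0.2
    t_paired: float = 0.06
    min_overlap_ratio: float = 0.3

    def __post_init__(self):
        for v in (self.max_mismatch_ratio, self.t_paired, self.min_overlap_ratio):
            if not 0 < v <= 1:
                raise ValueError("filter thresholds must lie in (0, 1]")


@dataclass
class Candidate:
    """A retrieved read together with its alignment to the anchor."""

    read: EncodedRead
    alignment: AlignmentResult


def _score_orientation(anchor: np.ndarray, cand: np.ndarray, min_overlap: int):
    """(shifts, overlaps, mismatches) for every shift meeting the overlap floor."""
    n, m = len(anchor), len(cand)
    lo, hi = min_overlap - m, n - min_overlap
    if hi < lo:
        return None
    padded = np.full(n + 2 * m, _PAD, dtype=np.uint8)
    padded[m : m + n] = anchor
    windows = sliding_window_view(padded, m)[lo + m : hi + m + 1]
    valid = (windows < 4) & (cand < 4)[None, :]
    overlaps = valid.sum(axis=1)
    mismatches = ((windows != cand[None, :]) & valid).sum(axis=1)
    shifts = np.arange(lo, hi + 1)
    keep = overlaps >= min_overlap
    return shifts[keep], overlaps[keep], mismatches[keep]


def align_shd(
    anchor: EncodedRead,
    candidate: EncodedRead,
    min_overlap_ratio: float = 0.3,
) -> AlignmentResult:
    """Best-ratio gapless alignment over all shifts and both orientations.

    Only shifts whose (N-excluded) overlap reaches ``min_overlap_ratio`` times
    the anchor length are considered; if none does the result is invalid.
    Ties on the ratio break towards the smallest ``|shift|``, then forward
    orientation.
    """
    a = anchor.codes
    min_overlap = max(1, math.ceil(min_overlap_ratio * len(a)))
    best = None
    for orientation, ccodes in (
        ("fwd", candidate.codes),
        ("rc", reverse_complement(candidate.codes)),
    ):
        scored = _score_orientation(a, ccodes, min_overlap)
        if scored is None:
            continue
        shifts, overlaps, mismatches = scored
        if len(shifts) == 0:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = mismatches / overlaps
        order = np.lexsort((np.abs(shifts), ratios))
        i = order[0]
        cand_best = (
            float(ratios[i]),
            abs(int(shifts[i])),
            0 if orientation == "fwd" else 1,
            int(shifts[i]),
            int(overlaps[i]),
            int(mismatches[i]),
            orientation,
        )
        if best is None or cand_best[:3] < best[:3]:
            best = cand_best
    if best is None:
        return AlignmentResult(0, 0, 0, "fwd", False)
    _, _, _, shift, overlap, mismatches, orientation = best
    return AlignmentResult(shift, overlap, mismatches, orientation, True)


def filter_single(
    cands: Sequence[Candidate], params: FilterParams
) -> list[Candidate]:
    """Keep candidates whose mismatch/overlap ratio does not surpass the cap."""
    return [
        c
        for c in cands
        if c.alignment.valid
        and c.alignment.mismatch_ratio <= params.max_mismatch_ratio
    ]


def filter_paired(
    cands_a0: Sequence[Candidate],
    cands_a1: Sequence[Candidate],
    params: FilterParams,
    mate_of=lambda read_id: read_id ^ 1,
) -> tuple[list[Candidate], list[Candidate]]:
    """Mate-aware candidate filter for an anchor pair.

    A candidate of one anchor whose mate is among the other anchor's
    candidates passes unconditionally — both fragments then almost surely
    stem from the same genomic region. Every other candidate passes only if
    its mismatch ratio is strictly below ``t_paired``.
    """
    ids0 = {c.read.read_id for c in cands_a0}
    ids1 = {c.read.read_id for c in cands_a1}

    def _apply(cands, other_ids):
        out = []
        for c in cands:
            if not c.alignment.valid:
                continue
            if mate_of(c.read.read_id) in other_ids:
                out.append(c)
            elif c.alignment.mismatch_ratio < params.t_paired:
                out.append(c)
        return out

    return _apply(cands_a0, ids1), _apply(cands_a1, ids0)
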