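"""Anchor-centered multiple sequence alignment and its iterative refinement.

The MSA is gapless: each member row is placed at its alignment shift, in the
style of the star-alignment approximation, with the anchor occupying columns
``[0, anchor_length)``. Per column and nucleotide the MSA stores a raw count
and a weight sum; a row's weight combines its alignment quality (rows with
more mismatches count less) with each base's Phred-derived reliability.  The
column *consensus* is the nucleotide with the greatest weight and the
*support* is the consensus' share of the column's total weight.

Refinement removes candidate rows that follow a different pattern than the
anchor at a strongly supported discordant column — typically rows drawn from
the other copy of an inexact repeat — and recomputes the consensus, for at
most five rounds, stopping early once a round removes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .align import Candidate
from .io_encodings import EncodedRead, reverse_complement

__all__ = ["MsaMember", "Msa", "RefinementParams", "build_msa", "refine_msa"]

# floor for the alignment factor so a surviving row is never voiceless
_ALIGN_FLOOR = 0.25


@dataclass
class MsaMember:
    read: EncodedRead
    shift: int
    orientation: str
    row_codes: np.ndarray  # anchor-oriented, N_CODE at N positions
    base_weights: np.ndarray  # per-base weight, 0.0 at N positions
    is_anchor: bool = False
    mismatch_ratio: float = 0.0


def _member_from(
    read: EncodedRead,
    shift: int,
    orientation: str,
    mismatch_ratio: float,
    use_quality: bool,
    is_anchor: bool = False,
) -> MsaMember:
    codes = read.codes
    qual = read.quality.astype(float)
    if orientation == "rc":
        codes = reverse_complement(codes)
        qual = qual[::-1]
    align_factor = max(1.0 - 3.0 * mismatch_ratio, _ALIGN_FLOOR)
    if use_quality:
        w = align_factor * (1.0 - np.power(10.0, -qual / 10.0))
    else:
        w = np.full(len(codes), align_factor)
    w = np.where(codes < 4, w, 0.0)
    return MsaMember(read, shift, orientation, codes, w, is_anchor, mismatch_ratio)


@dataclass
class Msa:
    """Column counts/weights over ``[first, last)`` in anchor coordinates."""

    anchor_length: int
    first: int
    last: int
    counts: np.ndarray  # (4, width) int64
    weights: np.ndarray  # (4, width) float64
    members: list = field(default_factory=list)

    @property
    def width(self) -> int:
        return self.last - self.first

    @property
    def anchor(self) -> MsaMember:
        return next(m for m in self.members if m.is_anchor)

    def column_of(self, anchor_coord: int) -> int:
        return anchor_coord - self.first

    def _add(self, member: MsaMember, sign: int = 1) -> None:
        cols = np.arange(len(member.row_codes)) + member.shift - self.first
        sel = member.row_codes < 4
        self.counts[member.row_codes[sel], cols[sel]] += sign
        self.weights[member.row_codes[sel], cols[sel]] += sign * member.base_weights[sel]

    def coverage(self) -> np.ndarray:
        """Reads contributing a non-N base, per column."""
        return self.counts.sum(axis=0)

    def consensus(self) -> np.ndarray:
        """Highest-weight nucleotide per column.

        Ties prefer the anchor's base on anchor-covered columns, else the
        lexicographically smallest nucleotide (conservative toward a no-op).
        """
        cons = np.argmax(self.weights, axis=0).astype(np.uint8)
        colmax = self.weights.max(axis=0)
        anchor = self.anchor
        a0 = self.column_of(0)
        acods = anchor.row_codes
        for j in np.flatnonzero(acods < 4):
            c = a0 + j
            if self.weights[acods[j], c] == colmax[c]:
                cons[c] = acods[j]
        return cons

    def support(self, cons: Optional[np.ndarray] = None) -> np.ndarray:
        """Relative weight of the consensus nucleotide, per column."""
        if cons is None:
            cons = self.consensus()
        total = self.weights.sum(axis=0)
        out = np.zeros(self.width)
        covered = total > 0
        out[covered] = self.weights[cons[covered], np.flatnonzero(covered)] / total[
            covered
        ]
        return out

    def remove_members(self, read_ids: set[int]) -> None:
        """Incrementally subtract the named candidate rows (anchor immune)."""
        survivors = []
        for m in self.members:
            if not m.is_anchor and m.read.read_id in read_ids:
                self._add(m, sign=-1)
            else:
                survivors.append(m)
        self.members = survivors

    def rebuild(self) -> "Msa":
        """From-scratch recomputation over the current member set (oracle)."""
        fresh = Msa(
            anchor_length=self.anchor_length,
            first=self.first,
            last=self.last,
            counts=np.zeros_like(self.counts),
            weights=np.zeros_like(self.weights),
            members=list(self.members),
        )
        for m in fresh.members:
            fresh._add(m)
        return fresh


def build_msa(
    anchor: EncodedRead,
    candidates: Sequence[Candidate],
    use_quality: bool = True,
) -> Msa:
    """Stack the anchor and its filtered candidates into column profiles."""
    alen = anchor.length
    first = min([0] + [c.alignment.shift for c in candidates])
    last = max([alen] + [c.alignment.shift + c.read.length for c in candidates])
    msa = Msa(
        anchor_length=alen,
        first=first,
        last=last,
        counts=np.zeros((4, last - first), dtype=np.int64),
        weights=np.zeros((4, last - first)),
    )
    msa.members.append(
        _member_from(anchor, 0, "fwd", 0.0, use_quality, is_anchor=True)
    )
    for c in candidates:
        msa.members.append(
            _member_from(
                c.read,
                c.alignment.shift,
                c.alignment.orientation,
                c.alignment.mismatch_ratio,
                use_quality,
            )
        )
    for m in msa.members:
        msa._add(m)
    return msa


@dataclass(frozen=True)
class RefinementParams:
    estimated_coverage: float
    frequency_factor: float = 0.3
    max_iterations: int = 5

    @property
    def count_threshold(self) -> float:
        return self.frequency_factor * self.estimated_coverage


def refine_msa(msa: Msa, params: RefinementParams) -> tuple[Msa, list[set[int]]]:
    """Iteratively drop candidate rows with an off-anchor column pattern.

    Each round scans the anchor-covered columns for a non-consensus
    nucleotide ``X`` whose raw count reaches ``frequency_factor x estimated
    coverage``; among triggering columns only the one with the largest
    discordant count is acted on, since removals invalidate the consensus of
    the others.  If ``X`` matches the anchor's base there, rows covering the
    column *without* ``X`` are removed (the anchor's own pattern is the
    minority pattern being rescued); otherwise rows carrying ``X`` are
    removed.  The anchor row is never removed.  Returns the refined MSA and
    the per-iteration removed-id sets.
    """
    if params.estimated_coverage <= 0:
        raise ValueError("estimated_coverage must be positive")
    removed_per_iter: list[set[int]] = []
    a0 = msa.column_of(0)
    anchor = msa.anchor
    for _ in range(params.max_iterations):
        cons = msa.consensus()
        best = None  # (count, column, nucleotide)
        for j in range(msa.anchor_length):
            c = a0 + j
            for x in range(4):
                if x == cons[c]:
                    continue
                cnt = int(msa.counts[x, c])
                if cnt >= params.count_threshold and (
                    best is None or cnt > best[0]
                ):
                    best = (cnt, c, x)
        if best is None:
            break
        _, c, x = best
        anchor_base = anchor.row_codes[c - a0]
        to_remove: set[int] = set()
        for m in msa.members:
            if m.is_anchor:
                continue
            j = c - (m.shift - msa.first)
            if not (0 <= j < len(m.row_codes)) or m.row_codes[j] >= 4:
                continue
            carries_x = m.row_codes[j] == x
            if (x == anchor_base and not carries_x) or (
                x != anchor_base and carries_x
            ):
                to_remove.add(m.read.read_id)
        if not to_remove:
            break
        msa.remove_members(to_remove)
        removed_per_iter.append(to_remove)
    return msa, removed_per_iter
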