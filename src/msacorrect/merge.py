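"""Reconciliation of anchor and candidate corrections into final reads.

A read can be corrected once as an anchor and repeatedly as a candidate in
other anchors' MSAs.  With fewer than three candidate corrections the anchor
correction is trusted outright; with three or more, it is used only when all
candidate corrections agree with it, otherwise the read is left untouched.
A read with no anchor correction keeps its original sequence unless at least
three mutually identical candidate corrections exist.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .classic import CorrectionRecord
from .io_encodings import EncodedRead, encode_2bit, write_fastq

__all__ = ["MergeDecision", "merge_corrections", "write_output"]


@dataclass(frozen=True)
class MergeDecision:
    read_id: int
    decision: str  # anchor_used | candidates_agree | kept_original
    n_candidate_records: int


def _replace_sequence(read: EncodedRead, sequence: str) -> EncodedRead:
    if len(sequence) != read.length:
        raise ValueError("corrected sequence length differs from the read")
    packed, n_mask = encode_2bit(sequence)
    return EncodedRead(
        read_id=read.read_id,
        packed=packed,
        n_mask=n_mask,
        length=read.length,
        quality=read.quality,
        name=read.name,
        mate_id=read.mate_id,
    )


def merge_corrections(
    records: Iterable[CorrectionRecord],
    originals: Sequence[EncodedRead],
) -> tuple[list[EncodedRead], list[MergeDecision]]:
    """Group records by read and apply the reconciliation rules.

    ``originals`` must be indexed by ``read_id``.  The result preserves input
    order; the audit list records which rule fired for every read that had at
    least one record.
    """
    by_read: dict[int, dict] = {}
    n_reads = len(originals)
    for rec in records:
        if not 0 <= rec.read_id < n_reads:
            raise ValueError(f"correction record for unknown read id {rec.read_id}")
        slot = by_read.setdefault(rec.read_id, {"anchor": None, "candidates": []})
        if rec.kind == "anchor":
            if slot["anchor"] is not None:
                raise ValueError(f"read {rec.read_id} has two anchor corrections")
            slot["anchor"] = rec
        else:
            slot["candidates"].append(rec)

    final = list(originals)
    audit: list[MergeDecision] = []
    for read_id in sorted(by_read):
        slot = by_read[read_id]
        anchor: Optional[CorrectionRecord] = slot["anchor"]
        cands: list[CorrectionRecord] = slot["candidates"]
        chosen: Optional[str] = None
        decision = "kept_original"
        if anchor is not None:
            if len(cands) < 3:
                chosen, decision = anchor.corrected_sequence, "anchor_used"
            elif all(c.corrected_sequence == anchor.corrected_sequence for c in cands):
                chosen, decision = anchor.corrected_sequence, "anchor_used"
        else:
            # anchorless read: extend the >=3-agreement principle symmetrically
            if len(cands) >= 3 and all(
                c.corrected_sequence == cands[0].corrected_sequence for c in cands
            ):
                chosen, decision = cands[0].corrected_sequence, "candidates_agree"
        if chosen is not None and chosen != originals[read_id].sequence:
            final[read_id] = _replace_sequence(originals[read_id], chosen)
        elif chosen is not None:
            decision = decision  # no-op correction still counts as applied
        audit.append(MergeDecision(read_id, decision, len(cands)))
    return final, audit


def write_output(
    reads: Sequence[EncodedRead],
    path,
    paired_path=None,
) -> None:
    """Write final reads as FASTQ; with ``paired_path``, de-interleave mates."""
    if paired_path is None:
        write_fastq(reads, path)
    else:
        write_fastq(reads[0::2], path)
        write_fastq(reads[1::2], paired_path)
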