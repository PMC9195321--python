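"""Rule-based anchor and candidate correction from the refined MSA.

The MSA is classified as high- or low-quality from three aggregates over the
anchor-covered columns: minimum support, average support, minimum coverage.
High-quality MSAs replace the anchor with the column consensus outright and
additionally correct candidates lying close to the anchor's column range;
low-quality MSAs only touch anchor positions with overwhelming evidence
(support above 0.90 and at most two reads still carrying the anchor's base).
"""

from __future__ import annotations

from dataclasses import dataclass


from .io_encodings import EncodedRead, reverse_complement
from .msa import Msa

__all__ = [
    "MsaQuality",
    "QualityThresholds",
    "CorrectionRecord",
    "classify_msa",
    "consensus_string",
    "correct_anchor_classic",
    "correct_candidates",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class QualityThresholds:
    min_support: float = 0.75
    avg_support: float = 0.90
    min_coverage: float = 5.0


@dataclass(frozen=True)
class MsaQuality:
    min_support: float
    avg_support: float
    min_coverage: int
    is_high_quality: bool


@dataclass
class CorrectionRecord:
    """A proposed corrected sequence for one read.

    ``kind`` is ``"anchor"`` when the read was the MSA's center and
    ``"candidate"`` when it was corrected as a supporting read of some other
    anchor.  ``edits`` lists ``(position, old_base, new_base)`` in the read's
    own orientation and exactly characterizes corrected vs original.
    """

    read_id: int
    corrected_sequence: str
    kind: str
    edits: list[tuple[int, str, str]]


def _edits(original: str, corrected: str) -> list[tuple[int, str, str]]:
    return [
        (i, o, c) for i, (o, c) in enumerate(zip(original, corrected)) if o != c
    ]


def classify_msa(msa: Msa, thresholds: QualityThresholds) -> MsaQuality:
    """Aggregate support/coverage over anchor columns and threshold them."""
    cons = msa.consensus()
    support = msa.support(cons)
    coverage = msa.coverage()
    a0 = msa.column_of(0)
    sl = slice(a0, a0 + msa.anchor_length)
    min_sup = float(support[sl].min())
    avg_sup = float(support[sl].mean())
    min_cov = int(coverage[sl].min())
    hq = (
        min_sup >= thresholds.min_support
        and avg_sup >= thresholds.avg_support
        and min_cov >= thresholds.min_coverage
    )
    return MsaQuality(min_sup, avg_sup, min_cov, hq)


def consensus_string(msa: Msa, start_col: int, length: int) -> str:
    """Consensus bases over MSA columns ``[start_col, start_col + length)``."""
    cons = msa.consensus()
    return "".join(_BASES[cons[c]] for c in range(start_col, start_col + length))


def correct_anchor_classic(
    anchor: EncodedRead, msa: Msa, quality: MsaQuality
) -> CorrectionRecord:
    """Correct the MSA's center read by its column consensus.

    High-quality MSA: every anchor position becomes the consensus.
    Low-quality MSA: a position is changed only when the column's support
    exceeds 0.90 and no more than two reads still carry the anchor's base.
    """
    original = anchor.sequence
    a0 = msa.column_of(0)
    cons = msa.consensus()
    support = msa.support(cons)
    out = list(original)
    for j in range(anchor.length):
        c = a0 + j
        cons_base = _BASES[cons[c]]
        if quality.is_high_quality:
            out[j] = cons_base
        else:
            code = anchor.codes[j]
            anchor_count = int(msa.counts[code, c]) if code < 4 else 0
            if support[c] > 0.90 and anchor_count <= 2:
                out[j] = cons_base
    corrected = "".join(out)
    return CorrectionRecord(anchor.read_id, corrected, "anchor", _edits(original, corrected))


def correct_candidates(
    msa: Msa,
    quality: MsaQuality,
    margin: int = 15,
) -> list[CorrectionRecord]:
    """Candidate corrections from a high-quality MSA.

    Only candidates fully contained in ``[b - margin, e + margin)`` around
    the anchor's column range ``[b, e)`` are corrected (coverage decays with
    distance from the anchor, so far-flung columns are unreliable); the
    corrected sequence is the column consensus across the candidate's span,
    transformed back into the candidate's original orientation.
    """
    if not quality.is_high_quality:
        raise ValueError("candidate corrections require a high-quality MSA")
    records = []
    cons = msa.consensus()
    for m in msa.members:
        if m.is_anchor:
            continue
        begin, end = m.shift, m.shift + len(m.row_codes)
        if begin < -margin or end > msa.anchor_length + margin:
            continue
        cols = slice(msa.column_of(begin), msa.column_of(end))
        cons_codes = cons[cols]
        if m.orientation == "rc":
            cons_codes = reverse_complement(cons_codes)
        corrected = "".join(_BASES[b] for b in cons_codes)
        original = m.read.sequence
        records.append(
            CorrectionRecord(
                m.read.read_id, corrected, "candidate", _edits(original, corrected)
            )
        )
    return records
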