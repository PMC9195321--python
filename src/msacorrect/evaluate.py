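"""Correction-quality measurement against ground truth.

Per-base three-way comparison: for each base let ``u``, ``e``, ``c`` be the
uncorrected, error-free and corrected nucleotides at the same read position.
A correction is a true positive when ``u != e`` and ``e == c``; a false
positive when ``u == e`` and ``e != c``.  A base where ``u != e`` and the
corrector wrote neither ``u`` nor ``e`` is a *miscorrection* — the two
printed definitions do not cover it, so it is reported in its own column and
excluded from the FP-rate formula ``10^6 * FP / (FP + TP)``.

For real data without ground truth, the k-mer spectrum check counts *lost
true k-mers*: canonical k-mers present in both the uncorrected reads and the
reference genome but absent from the corrected reads, binned by their
coverage (multiplicity) in the uncorrected reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_encodings import EncodedRead

__all__ = [
    "EvalCounts",
    "KmerSpectrumReport",
    "compare_three_way",
    "fp_rate",
    "lost_true_kmers",
]


@dataclass(frozen=True)
class EvalCounts:
    TP: int
    FP: int
    FN: int
    TN: int
    miscorrections: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN + self.miscorrections

    @property
    def fp_rate_per_million(self) -> Optional[float]:
        if self.TP + self.FP == 0:
            return None
        return 1e6 * self.FP / (self.FP + self.TP)


def compare_three_way(
    uncorrected: Sequence[EncodedRead],
    error_free: Sequence[EncodedRead],
    corrected: Sequence[EncodedRead],
) -> EvalCounts:
    """Count TP/FP/FN/TN (and miscorrections) over all read bases."""
    if not (len(uncorrected) == len(error_free) == len(corrected)):
        raise ValueError("the three datasets differ in read count")
    tp = fp = fn = tn = mis = 0
    for u_read, e_read, c_read in zip(uncorrected, error_free, corrected):
        if not (u_read.length == e_read.length == c_read.length):
            raise ValueError(
                f"read {u_read.read_id}: lengths differ across the three files"
            )
        u, e, c = u_read.codes, e_read.codes, c_read.codes
        had_err = u != e
        tp += int(np.sum(had_err & (e == c)))
        fn += int(np.sum(had_err & (c == u)))
        mis += int(np.sum(had_err & (c != u) & (c != e)))
        fp += int(np.sum(~had_err & (e != c)))
        tn += int(np.sum(~had_err & (c == u)))
    return EvalCounts(tp, fp, fn, tn, mis)


def fp_rate(counts: EvalCounts) -> float:
    """False positives per million corrections, ``10^6 * FP / (FP + TP)``."""
    if counts.TP + counts.FP == 0:
        raise ValueError("no corrections were made; FP rate undefined")
    return 1e6 * counts.FP / (counts.FP + counts.TP)


# ---------------------------------------------------------------------------
# k-mer spectrum


@dataclass(frozen=True)
class KmerSpectrumReport:
    k: int
    # lost_by_coverage[c] = distinct lost true k-mers with uncorrected-read
    # multiplicity c, for c in 1..max_coverage
    lost_by_coverage: dict[int, int]

    @property
    def total_lost(self) -> int:
        return sum(self.lost_by_coverage.values())


def _canonical_kmer_counts(reads: Sequence[EncodedRead], k: int) -> dict[int, int]:
    from .minhash import canonical_kmer_codes

    counts: dict[int, int] = {}
    for r in reads:
        for code in canonical_kmer_codes(r.codes, k):
            code = int(code)
            counts[code] = counts.get(code, 0) + 1
    return counts


def _genome_kmer_set(sequences: Sequence[str], k: int) -> set[int]:
    from .io_encodings import EncodedRead
    from .minhash import canonical_kmer_codes

    kmers: set[int] = set()
    for seq in sequences:
        codes = EncodedRead.from_sequence(seq).codes
        kmers.update(int(c) for c in canonical_kmer_codes(codes, k))
    return kmers


def lost_true_kmers(
    uncorrected: Sequence[EncodedRead],
    corrected: Sequence[EncodedRead],
    reference: Sequence[str],
    k: int = 21,
    max_coverage: int = 10,
) -> KmerSpectrumReport:
    """Distinct true k-mers lost by correction, binned by read coverage.

    ``reference`` is the genome as one or more sequences.  A k-mer counts as
    lost when it occurs in the uncorrected reads and in the reference but in
    the corrected reads not at all; its bin is its multiplicity in the
    uncorrected reads (bins above ``max_coverage`` are not reported — loss
    of well-covered k-mers is vanishingly rare and the low-coverage tail is
    the diagnostic part of the spectrum).
    """
    unc = _canonical_kmer_counts(uncorrected, k)
    cor = _canonical_kmer_counts(corrected, k)
    ref = _genome_kmer_set(reference, k)
    lost = {c: 0 for c in range(1, max_coverage + 1)}
    for kmer, cov in unc.items():
        if cov <= max_coverage and kmer in ref and kmer not in cor:
            lost[cov] += 1
    return KmerSpectrumReport(k=k, lost_by_coverage=lost)
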