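"""FASTQ/FASTA I/O, 2-bit sequence encoding and quality-score binning.

Reads are held in memory as :class:`EncodedRead`: the nucleotide sequence is
packed two bits per base with a separate mask marking ``N`` positions (an ``N``
is stored as the code for ``A`` in the packed array but never treated as
evidence downstream), qualities are Phred integers, and paired-end mates are
interleaved so that reads ``2*i`` and ``2*i + 1`` form a pair.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "EncodedRead",
    "QualityBinning",
    "FastqParseError",
    "PairingError",
    "encode_2bit",
    "decode_2bit",
    "pack_codes",
    "unpack_codes",
    "bin_quality",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
]

_BASES = "ACGT"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
# N sentinel used on the *unpacked* side; packed storage keeps 2 bits + mask.
N_CODE = 4


class FastqParseError(ValueError):
    """Malformed FASTQ record; the message names the offending record."""


class PairingError(ValueError):
    """Paired input files disagree (unequal record counts)."""


def pack_codes(codes: np.ndarray) -> np.ndarray:
    """Pack an array of 2-bit base codes (values 0..3) four to a byte."""
    codes = np.asarray(codes, dtype=np.uint8)
    pad = (-len(codes)) % 4
    if pad:
        codes = np.concatenate([codes, np.zeros(pad, dtype=np.uint8)])
    c = codes.reshape(-1, 4)
    return (c[:, 0] << 6) | (c[:, 1] << 4) | (c[:, 2] << 2) | c[:, 3]


def unpack_codes(packed: np.ndarray, length: int) -> np.ndarray:
    """Inverse of :func:`pack_codes`."""
    packed = np.asarray(packed, dtype=np.uint8)
    out = np.empty(len(packed) * 4, dtype=np.uint8)
    out[0::4] = (packed >> 6) & 3
    out[1::4] = (packed >> 4) & 3
    out[2::4] = (packed >> 2) & 3
    out[3::4] = packed & 3
    return out[:length]


def encode_2bit(sequence: str) -> tuple[np.ndarray, np.ndarray]:
    """Encode a string over ``{A,C,G,T,N}`` as (packed 2-bit array, N mask)."""
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    codes = np.zeros(len(arr), dtype=np.uint8)
    n_mask = arr == ord("N")
    known = np.zeros(len(arr), dtype=bool)
    for base, code in _CODE.items():
        sel = arr == ord(base)
        codes[sel] = code
        known |= sel
    bad = ~(known | n_mask)
    if bad.any():
        pos = int(np.flatnonzero(bad)[0])
        raise ValueError(f"invalid nucleotide {sequence[pos]!r} at position {pos}")
    return pack_codes(codes), n_mask


def decode_2bit(packed: np.ndarray, n_mask: np.ndarray, length: int) -> str:
    codes = unpack_codes(packed, length)
    chars = np.frombuffer(("ACGT".encode("ascii")), dtype=np.uint8)[codes].copy()
    chars[n_mask] = ord("N")
    return chars.tobytes().decode("ascii")


@dataclass
class EncodedRead:
    """A sequencing read with 2-bit packed sequence, N mask and qualities.

    ``codes`` exposes the unpacked per-base view used by alignment and MSA
    construction: values 0..3 for A,C,G,T and 4 (:data:`N_CODE`) for N.
    """

    read_id: int
    packed: np.ndarray
    n_mask: np.ndarray
    length: int
    quality: np.ndarray
    name: str = ""
    mate_id: Optional[int] = None
    _codes: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    @classmethod
    def from_sequence(
        cls,
        sequence: str,
        quality: Optional[Sequence[int]] = None,
        read_id: int = 0,
        name: str = "",
        mate_id: Optional[int] = None,
    ) -> "EncodedRead":
        packed, n_mask = encode_2bit(sequence)
        if quality is None:
            quality = np.full(len(sequence), 40, dtype=np.uint8)
        quality = np.asarray(quality, dtype=np.uint8)
        if len(quality) != len(sequence):
            raise ValueError("sequence and quality lengths differ")
        return cls(read_id, packed, n_mask, len(sequence), quality, name, mate_id)

    @property
    def codes(self) -> np.ndarray:
        """Unpacked base codes with N positions set to :data:`N_CODE`."""
        if self._codes is None:
            c = unpack_codes(self.packed, self.length)
            c[self.n_mask] = N_CODE
            self._codes = c
        return self._codes

    @property
    def sequence(self) -> str:
        return decode_2bit(self.packed, self.n_mask, self.length)

    def __len__(self) -> int:
        return self.length


def reverse_complement(codes: np.ndarray) -> np.ndarray:
    """Reverse-complement an unpacked code array (N stays N)."""
    out = codes[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


# ---------------------------------------------------------------------------
# Quality binning


@dataclass(frozen=True)
class QualityBinning:
    """Lossy Phred-score binning (1 or 2 bits per base) or identity.

    ``boundaries`` are upper-exclusive thresholds: bin ``j`` holds scores
    ``boundaries[j-1] <= q < boundaries[j]`` and maps to ``representative[j]``.
    """

    mode: str  # raw8 | bins2 | bins1
    boundaries: tuple[int, ...]
    representatives: tuple[int, ...]

    @classmethod
    def raw8(cls) -> "QualityBinning":
        return cls("raw8", (), ())

    @classmethod
    def bins2(cls) -> "QualityBinning":
        # 2 bits -> 4 bins; conventional Illumina strata at Q10/Q20/Q30.
        return cls("bins2", (10, 20, 30), (5, 15, 25, 37))

    @classmethod
    def bins1(cls) -> "QualityBinning":
        # 1 bit -> 2 bins split at Q20.
        return cls("bins1", (20,), (6, 37))

    @classmethod
    def from_bits(cls, bits: int) -> "QualityBinning":
        if bits == 8:
            return cls.raw8()
        if bits == 2:
            return cls.bins2()
        if bits == 1:
            return cls.bins1()
        raise ValueError(f"unsupported quality width: {bits} bits")


def bin_quality(q, binning: QualityBinning):
    """Map Phred score(s) to the representative of their bin.

    Accepts a scalar or an array; ``raw8`` is the identity.
    """
    arr = np.asarray(q)
    if arr.min() < 0 or arr.max() > 93:
        raise ValueError("Phred score out of range 0..93")
    if binning.mode == "raw8":
        return q
    idx = np.digitize(arr, binning.boundaries)
    reps = np.asarray(binning.representatives, dtype=np.uint8)
    out = reps[idx]
    if np.isscalar(q) or arr.ndim == 0:
        return int(out)
    return out


# ---------------------------------------------------------------------------
# FASTQ / FASTA


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _parse_fastq_records(path) -> list:
    records = []
    with _open_text(path) as handle:
        try:
            for i, rec in enumerate(SeqIO.parse(handle, "fastq")):
                records.append(rec)
        except ValueError as exc:
            raise FastqParseError(
                f"{path}: malformed FASTQ near record {len(records) + 1}: {exc}"
            ) from exc
    return records


def read_fastq(
    path,
    paired_path=None,
    binning: Optional[QualityBinning] = None,
) -> list[EncodedRead]:
    """Load FASTQ (optionally gzipped) into a list of :class:`EncodedRead`.

    With ``paired_path`` the two files are interleaved so mates occupy indices
    ``2*i`` / ``2*i + 1`` and carry each other's index in ``mate_id``.
    """
    rec1 = _parse_fastq_records(path)
    if paired_path is None:
        reads = []
        for i, rec in enumerate(rec1):
            reads.append(_record_to_read(rec, i, None, binning))
        return reads
    rec2 = _parse_fastq_records(paired_path)
    if len(rec1) != len(rec2):
        raise PairingError(
            f"paired files differ in record count: {len(rec1)} vs {len(rec2)}"
        )
    reads = []
    for i, (a, b) in enumerate(zip(rec1, rec2)):
        reads.append(_record_to_read(a, 2 * i, 2 * i + 1, binning))
        reads.append(_record_to_read(b, 2 * i + 1, 2 * i, binning))
    return reads


def _record_to_read(rec, read_id, mate_id, binning) -> EncodedRead:
    qual = np.asarray(rec.letter_annotations["phred_quality"], dtype=np.uint8)
    if binning is not None and binning.mode != "raw8":
        qual = bin_quality(qual, binning)
    read = EncodedRead.from_sequence(
        str(rec.seq), qual, read_id=read_id, name=rec.description, mate_id=mate_id
    )
    return read


def write_fastq(reads: Iterable[EncodedRead], path) -> None:
    """Write reads as Sanger FASTQ, preserving names and qualities."""
    with _open_text(path, "wt") as out:
        for r in reads:
            qual = "".join(chr(int(q) + 33) for q in r.quality)
            name = r.name or f"read{r.read_id}"
            out.write(f"@{name}\n{r.sequence}\n+\n{qual}\n")


def read_fasta(path) -> list[tuple[str, str]]:
    """Return (name, sequence) tuples from a FASTA file (optionally gzipped)."""
    with _open_text(path) as handle:
        return [(rec.description, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]


def write_fasta(entries: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    with _open_text(path, "wt") as out:
        for name, seq in entries:
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")
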