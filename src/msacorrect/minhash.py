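"""Minhash read signatures and the multi-table candidate index.

Every read is sketched by ``h`` independent hash functions: each function is
applied to every canonical k-mer of the read and the per-function minimum is
kept, giving a length-``h`` signature that is invariant under reverse
complement. Signature slot ``l`` is the key under which the read id is stored
in hash table ``l``; querying a read unions the buckets its own signature
addresses, which retrieves reads likely to share genomic origin with it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_encodings import EncodedRead, N_CODE

__all__ = [
    "ReadSignature",
    "MinhashIndex",
    "SignatureUndefined",
    "make_seeds",
    "canonical_kmer_codes",
    "compute_signature",
    "build_index",
    "query_candidates",
]

_U64 = np.uint64


class SignatureUndefined(ValueError):
    """Read has no valid k-mer (too short, or all windows contain N)."""


def make_seeds(h: int, seed: int) -> np.ndarray:
    """Derive ``h`` 64-bit per-function seeds from one integer seed."""
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2**63, size=h, dtype=np.uint64)


def splitmix64(x: np.ndarray) -> np.ndarray:
    """64-bit avalanche finalizer (splitmix64); vectorized over uint64."""
    z = x.astype(_U64, copy=True)
    z ^= z >> _U64(30)
    z *= _U64(0xBF58476D1CE4E5B9)
    z ^= z >> _U64(27)
    z *= _U64(0x94D049BB133111EB)
    z ^= z >> _U64(31)
    return z


def _rolling_kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """2-bit integer code of each k-mer window (first base most significant)."""
    n = len(codes) - k + 1
    vals = np.zeros(n, dtype=_U64)
    c = np.where(codes < 4, codes, 0).astype(_U64)
    for j in range(k):
        vals = (vals << _U64(2)) | c[j : j + n]
    return vals


def canonical_kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical (strand-invariant) integer codes of a read's valid k-mers.

    Windows containing an N are skipped. Returns an empty array when the read
    is shorter than ``k`` or has no N-free window.
    """
    if len(codes) < k:
        return np.empty(0, dtype=_U64)
    fwd = _rolling_kmer_codes(codes, k)
    rc_read = codes[::-1].copy()
    acgt = rc_read < 4
    rc_read[acgt] = 3 - rc_read[acgt]
    rev = _rolling_kmer_codes(rc_read, k)[::-1]
    canon = np.minimum(fwd, rev)
    n_flag = (codes == N_CODE).astype(np.int32)
    if n_flag.any():
        win = np.convolve(n_flag, np.ones(k, dtype=np.int32), mode="valid")
        canon = canon[win == 0]
    return canon


@dataclass(frozen=True)
class ReadSignature:
    """Per-hash-function minima over a read's canonical k-mers."""

    values: np.ndarray  # shape (h,)

    def __len__(self) -> int:
        return len(self.values)


def compute_signature(read: EncodedRead, k: int, seeds: np.ndarray) -> ReadSignature:
    canon = canonical_kmer_codes(read.codes, k)
    if len(canon) == 0:
        raise SignatureUndefined(
            f"read {read.read_id} has no valid {k}-mer (length {read.length})"
        )
    hashed = splitmix64(canon[None, :] ^ seeds[:, None])
    return ReadSignature(hashed.min(axis=1))


@dataclass
class MinhashIndex:
    """``h`` hash tables mapping signature slot values to sets of read ids."""

    k: int
    seeds: np.ndarray
    tables: list[dict] = field(default_factory=list)
    unindexable: set = field(default_factory=set)

    @property
    def h(self) -> int:
        return len(self.seeds)

    def insert(self, read: EncodedRead) -> None:
        try:
            sig = compute_signature(read, self.k, self.seeds)
        except SignatureUndefined:
            self.unindexable.add(read.read_id)
            return
        for l, key in enumerate(sig.values):
            self.tables[l].setdefault(int(key), []).append(read.read_id)


def build_index(
    reads: Sequence[EncodedRead],
    k: int = 20,
    h: int = 48,
    seeds: Optional[np.ndarray] = None,
    seed: int = 0,
) -> MinhashIndex:
    """Insert every read into all ``h`` tables keyed by its signature."""
    if seeds is None:
        seeds = make_seeds(h, seed)
    index = MinhashIndex(k=k, seeds=seeds, tables=[{} for _ in range(len(seeds))])
    for read in reads:
        index.insert(read)
    return index


def query_candidates(
    index: MinhashIndex,
    read: EncodedRead,
    max_candidates: int = 1000,
) -> set[int]:
    """Union the buckets addressed by the read's signature; self excluded.

    If the union exceeds ``max_candidates``, the contributions of the most
    populous buckets are dropped first until the cap is met — oversized
    buckets are dominated by repeats and carry little locating information.
    """
    try:
        sig = compute_signature(read, index.k, index.seeds)
    except SignatureUndefined:
        return set()
    buckets = []
    for l, key in enumerate(sig.values):
        buckets.append(index.tables[l].get(int(key), []))
    result: set[int] = set().union(*buckets) if buckets else set()
    result.discard(read.read_id)
    if len(result) > max_candidates:
        for b in sorted(buckets, key=len, reverse=True):
            kept = [bb for bb in buckets if bb is not b]
            result = set().union(*kept) if kept else set()
            result.discard(read.read_id)
            buckets = kept
            if len(result) <= max_candidates:
                break
    return result
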