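"""Synthetic genomes and Illumina-like paired-end reads with substitution errors.

The generator emulates the statistical structure a short-read corrector
exploits: ~100 bp reads at a chosen fold-coverage, per-base substitution
errors whose probability follows the read's Phred profile (quality degrades
towards the 3' end), paired reads drawn from opposite ends of a fragment, and
an error-free twin of every output so per-base ground truth is available.
Indels, adapters and PCR artifacts are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io_encodings import EncodedRead, reverse_complement

__all__ = ["SimulationConfig", "SimulatedErrors", "simulate_genome", "simulate_reads"]


@dataclass
class SimulationConfig:
    genome_length: int = 10_000
    coverage: float = 30.0
    read_length: int = 100
    error_rate: float = 0.01
    paired: bool = True
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    seed: int = 0
    # (copies, unit_length, divergence) for planted inexact repeats
    repeat_spec: Optional[tuple[int, int, float]] = None
    # Phred profile: mean degrades linearly q_start -> q_end along the read
    quality_start: float = 28.0
    quality_sd: float = 3.0
    quality_end: float = 18.0

    def n_reads(self) -> int:
        n = math.ceil(self.genome_length * self.coverage / self.read_length)
        if self.paired and n % 2:
            n += 1
        return n


@dataclass
class SimulatedErrors:
    """Ground-truth error log: one row per planted substitution."""

    read_id: np.ndarray
    position: np.ndarray
    true_base: np.ndarray  # characters
    observed_base: np.ndarray

    def __len__(self) -> int:
        return len(self.read_id)

    def to_tsv(self, path) -> None:
        with open(path, "w") as out:
            out.write("read_id\tposition\ttrue_base\tobserved_base\n")
            for i in range(len(self.read_id)):
                out.write(
                    f"{self.read_id[i]}\t{self.position[i]}\t"
                    f"{self.true_base[i]}\t{self.observed_base[i]}\n"
                )


def simulate_genome(config: SimulationConfig) -> str:
    """Uniform-random genome over ACGT, optionally with planted inexact repeats.

    A repeat spec ``(copies, unit_length, divergence)`` overwrites ``copies``
    evenly spaced windows with near-identical copies of one random unit, each
    copy mutated independently at rate ``divergence`` with at least one
    difference enforced so copies are inexact.
    """
    if config.genome_length <= 0:
        raise ValueError("genome_length must be positive")
    rng = np.random.default_rng(config.seed)
    genome = rng.integers(0, 4, size=config.genome_length, dtype=np.uint8)
    if config.repeat_spec is not None:
        copies, unit_len, divergence = config.repeat_spec
        if unit_len > config.genome_length or copies * unit_len > config.genome_length:
            raise ValueError("repeat unit(s) longer than genome")
        unit = rng.integers(0, 4, size=unit_len, dtype=np.uint8)
        slot = config.genome_length // copies
        for c in range(copies):
            copy = unit.copy()
            n_mut = max(1, int(round(divergence * unit_len)))
            pos = rng.choice(unit_len, size=n_mut, replace=False)
            copy[pos] = (copy[pos] + rng.integers(1, 4, size=n_mut)) % 4
            start = c * slot
            genome[start : start + unit_len] = copy
    return "".join("ACGT"[b] for b in genome)


def _draw_qualities(rng, n_reads: int, read_length: int, cfg: SimulationConfig):
    pos = np.arange(read_length)
    mean = cfg.quality_start + (cfg.quality_end - cfg.quality_start) * pos / max(
        read_length - 1, 1
    )
    q = rng.normal(mean, cfg.quality_sd, size=(n_reads, read_length))
    return np.clip(np.rint(q), 2, 41).astype(np.uint8)


def simulate_reads(
    genome: str, config: SimulationConfig
) -> tuple[list[EncodedRead], list[EncodedRead], SimulatedErrors]:
    """Draw reads from ``genome`` and plant substitution errors.

    Returns ``(erroneous reads, error-free twin, error log)``. Fragment start
    positions are uniform; in paired mode mate 1 reads the fragment's 5' end
    forward and mate 2 the 3' end reverse-complemented, and mates are
    interleaved at indices ``2*i`` / ``2*i + 1``.

    Error placement: each base's substitution probability is proportional to
    ``10**(-Q/10)`` for its drawn Phred score ``Q``, rescaled so the dataset
    mean equals ``error_rate`` exactly in expectation (the raw Phred profile
    only fixes the *shape* of the error distribution along the read).
    """
    if config.coverage <= 0:
        raise ValueError("coverage must be positive")
    L = len(genome)
    rl = config.read_length
    if rl > L:
        raise ValueError("read_length exceeds genome length")
    rng = np.random.default_rng(config.seed + 1)
    gcodes = np.frombuffer(genome.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    gcodes = lut[gcodes]

    n_reads = config.n_reads()
    seqs = np.empty((n_reads, rl), dtype=np.uint8)
    if config.paired:
        n_frag = n_reads // 2
        insert = np.clip(
            np.rint(rng.normal(config.insert_mean, config.insert_sd, size=n_frag)),
            rl,
            L,
        ).astype(np.int64)
        start = (rng.random(n_frag) * (L - insert + 1)).astype(np.int64)
        for f in range(n_frag):
            s, ins = start[f], insert[f]
            seqs[2 * f] = gcodes[s : s + rl]
            seqs[2 * f + 1] = reverse_complement(gcodes[s + ins - rl : s + ins])
    else:
        start = (rng.random(n_reads) * (L - rl + 1)).astype(np.int64)
        for i in range(n_reads):
            seqs[i] = gcodes[start[i] : start[i] + rl]

    quals = _draw_qualities(rng, n_reads, rl, config)
    base_p = np.power(10.0, -quals.astype(float) / 10.0)
    if config.error_rate > 0:
        p = np.minimum(base_p * (config.error_rate / base_p.mean()), 0.75)
    else:
        p = np.zeros_like(base_p)
    flip = rng.random(p.shape) < p
    observed = seqs.copy()
    # substitute to a uniformly random *different* base
    observed[flip] = (seqs[flip] + rng.integers(1, 4, size=int(flip.sum()))) % 4

    rid, pos = np.nonzero(flip)
    bases = np.array(list("ACGT"))
    log = SimulatedErrors(
        read_id=rid.astype(np.int64),
        position=pos.astype(np.int64),
        true_base=bases[seqs[rid, pos]],
        observed_base=bases[observed[rid, pos]],
    )

    def _to_reads(mat: np.ndarray) -> list[EncodedRead]:
        reads = []
        for i in range(n_reads):
            mate = (i ^ 1) if config.paired else None
            seq = "".join("ACGT"[b] for b in mat[i])
            reads.append(
                EncodedRead.from_sequence(
                    seq, quals[i], read_id=i, name=f"sim_{i}", mate_id=mate
                )
            )
        return reads

    return _to_reads(observed), _to_reads(seqs), log
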