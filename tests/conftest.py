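import numpy as np
import pytest

import msacorrect as mc


@pytest.fixture(scope="session")
def small_simulation():
    """2 kb genome, 30x paired reads at 1% error: shared across tests."""
    cfg = mc.SimulationConfig(genome_length=2_000, coverage=30.0, seed=11)
    genome = mc.simulate_genome(cfg)
    reads, perfect, log = mc.simulate_reads(genome, cfg)
    return genome, reads, perfect, log, cfg


def random_read(rng, length, read_id=0, with_n=False):
    bases = "ACGTN" if with_n else "ACGT"
    probs = [0.24, 0.24, 0.24, 0.24, 0.04] if with_n else None
    seq = "".join(rng.choice(list(bases), p=probs) for _ in range(length))
    qual = rng.integers(2, 41, size=length)
    return mc.EncodedRead.from_sequence(seq, qual, read_id=read_id)
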