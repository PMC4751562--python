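import numpy as np
import pytest

from rawmeth import BsSimConfig, SequenceRead
from rawmeth.bssim import assign_methylation, emit_reads, simulate_genome


def make_read(bases: str, quals=None, read_id: str = "r") -> SequenceRead:
    if quals is None:
        quals = np.full(len(bases), 40)
    return SequenceRead(read_id, bases, quals)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest simulated dataset shared across tests: 100 kb genome at
    GC 0.40 with distinct per-context methylation, 5,000 x 50 bp reads."""
    config = BsSimConfig(
        genome_length=100_000,
        gc_content=0.40,
        methylation={"CPG": 0.70, "CHG": 0.30, "CHH": 0.05},
        n_reads=5_000,
        read_length=50,
        seed=7,
    )
    genome = assign_methylation(simulate_genome(config))
    reads, provenance = emit_reads(genome)
    return {
        "config": config,
        "genome": genome,
        "reads": reads,
        "provenance": provenance,
        "realized": genome.realized_levels(),
        "realized_gc": genome.realized_gc(),
    }
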