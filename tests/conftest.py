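import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

from metapnps.dnds import GeneModel
from metapnps.pileup import Pileup
from metapnps.simulate import SimulationConfig, simulate_reads, synthetic_genome


@pytest.fixture
def small_genome():
    """A ~2 kb genome with 5 genes on mixed strands."""
    return synthetic_genome(5, mean_gene_codons=100, sd_gene_codons=20, seed=11)


@pytest.fixture
def simulated_instance(tmp_path, small_genome):
    """Genome + error-prone reads + truth SAM, run through nothing yet."""
    genome, genes = small_genome
    cfg = SimulationConfig(
        n_reads=600,
        length_mean=90,
        substitution_rate=0.004,
        seed=5,
    )
    fastq = tmp_path / "reads.fastq"
    sam = tmp_path / "reads.sam"
    simulate_reads({"synthref": genome}, cfg, str(fastq), str(sam))
    return genome, genes, str(sam)


def make_pileup(counts_by_pos: dict[int, dict[str, int]], length: int,
                reference_id: str = "ref") -> Pileup:
    """Build a Pileup directly from {position: {base: count}}."""
    counts = np.zeros((4, length), dtype=np.int32)
    for pos, col in counts_by_pos.items():
        for base, cnt in col.items():
            counts["ACGT".index(base), pos] = cnt
    return Pileup(reference_id, counts)


def uniform_pileup(seq: str, depth: int, reference_id: str = "ref") -> Pileup:
    """Every position covered at ``depth`` by the sequence's own base."""
    counts = np.zeros((4, len(seq)), dtype=np.int32)
    for i, b in enumerate(seq):
        if b in "ACGT":
            counts["ACGT".index(b), i] = depth
    return Pileup(reference_id, counts)


@pytest.fixture
def gene_factory():
    def make(start, end, strand="+", locus="g1", category="core", reference_id="ref"):
        return GeneModel(locus=locus, reference_id=reference_id, start=start,
                         end=end, strand=strand, category=category)
    return make
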