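import numpy as np
import pytest

from proipseq.genes import GeneModel
from proipseq.simulate import SimConfig, simulate_gene_set, simulate_sample_reads
from proipseq.tracks import EndTrack, FIVE_PRIME, THREE_PRIME, reads_to_end_track


def make_track(entries, end_kind=THREE_PRIME, genome="primary", chrom_sizes=None, metadata=None):
    """EndTrack from {(chrom, strand): {pos: count}} literals."""
    data = {}
    for key, counts in entries.items():
        pos = np.array(sorted(counts), dtype=np.int64)
        cnt = np.array([float(counts[p]) for p in pos.tolist()])
        data[key] = (pos, cnt)
    return EndTrack(genome, end_kind, data, metadata or {}, chrom_sizes)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_genes=30, genome_length=1_500_000, reads_per_sample=20_000,
        n_long_genes=1, long_gene_length=160_000, seed=7,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    genes, truth = simulate_gene_set(small_config)
    sim = simulate_sample_reads(genes, truth, small_config, "unPh", "NHS")
    return genes, truth, sim


@pytest.fixture(scope="session")
def small_tracks(small_config, small_experiment):
    genes, truth, sim = small_experiment
    sizes = {"chrSim1": small_config.genome_length}
    five = reads_to_end_track(sim.alignments, FIVE_PRIME, chrom_sizes=sizes)
    three = reads_to_end_track(sim.alignments, THREE_PRIME, chrom_sizes=sizes)
    return five, three


@pytest.fixture
def simple_gene():
    return GeneModel("gplus", "chr1", "+", 1000, 11000)


@pytest.fixture
def minus_gene():
    return GeneModel("gminus", "chr1", "-", 1000, 11000)
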