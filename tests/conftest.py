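import numpy as np
import pytest

from g4prom.sequence_io import GenomicSequence
from g4prom.synthetic_data import SimConfig, simulate_expression, simulate_genome


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_dna(rng, length, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


@pytest.fixture
def small_config():
    """A small but complete simulated study (fast enough for many tests)."""
    return SimConfig(seed=42, n_genes=60, window=2000, promoter_len=4200,
                     g4_gene_fraction=0.6, de_fraction=0.2)


@pytest.fixture
def small_dataset(small_config):
    seqs, anchors, truth = simulate_genome(small_config)
    expr, de_truth, probe_to_gene = simulate_expression(small_config, truth)
    return small_config, seqs, anchors, truth, expr, de_truth, probe_to_gene


@pytest.fixture
def seq_factory():
    return lambda seq_id, bases: GenomicSequence(seq_id, bases)
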