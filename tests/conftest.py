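import numpy as np
import pytest

from mitotx import fixtures
from mitotx.synthetic import SimConfig, simulate_genome, simulate_reads

GENOME_LENGTH = fixtures.GENOME_LENGTH


@pytest.fixture(scope="session")
def refined_ann():
    return fixtures.refined_annotation()


@pytest.fixture(scope="session")
def dna_ann():
    return fixtures.dna_annotation()


@pytest.fixture(scope="session")
def sim_bundle():
    """One medium-depth simulation shared across tests (seeded)."""
    config = SimConfig(seed=11, n_reads=2000)
    genome, annotation, repeat_truth = simulate_genome(config)
    alignments, truth, seqs = simulate_reads(genome, annotation, config)
    return {
        "config": config,
        "genome": genome,
        "annotation": annotation,
        "repeat_truth": repeat_truth,
        "alignments": alignments,
        "truth": truth,
        "seqs": seqs,
    }
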