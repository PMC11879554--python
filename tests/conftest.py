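import numpy as np
import pytest

from asekit.simulate import (
    SimulationConfig,
    generate_haplotype_pair,
    simulate_expression,
)


@pytest.fixture(scope="session")
def small_genome():
    """A 2-chromosome-pair, 100-locus genome with default divergence."""
    config = SimulationConfig(
        n_chromosome_pairs=2, n_loci_per_chromosome=50, allelic_fraction=0.8,
        seed=7,
    )
    genes_a, genes_b, cds_a, cds_b, blocks, truth = generate_haplotype_pair(config)
    return {
        "config": config,
        "genes_a": genes_a,
        "genes_b": genes_b,
        "cds_a": cds_a,
        "cds_b": cds_b,
        "blocks": blocks,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_expression(small_genome):
    counts, lengths = simulate_expression(
        small_genome["config"], small_genome["truth"]
    )
    return counts, lengths


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
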