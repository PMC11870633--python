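import numpy as np
import pytest

from evani.simulate import SimConfig, evolve, patristic_matrix, sample_species_tree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def small_sim():
    """A small substitution-only simulated dataset shared across tests."""
    cfg = SimConfig(
        n_leaves=6, mutation_rate=20.0, n_genes=10, gene_len=500,
        indel_rate=0.0, seed=77,
    )
    tree = sample_species_tree(cfg)
    genomes, homology = evolve(tree, cfg)
    return cfg, tree, genomes, homology, patristic_matrix(tree)
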