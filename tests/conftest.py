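import numpy as np
import pytest

from defcom import synthetic as syn


@pytest.fixture(scope="session")
def toy_genomes():
    """Three small genomes, one pair sharing a 30% block at 95% identity."""
    design = syn.SyntheticDesign(
        n_species=3,
        genome_length_per_species=1000,
        genes_per_species=8,
        puls_per_species=2,
        homology_blocks=[syn.HomologyBlock(("sp01", "sp02"), 0.3, 95.0)],
        seed=11,
    )
    return syn.generate_genomes(design)


@pytest.fixture(scope="session")
def shared_block_genomes():
    """Two of three species share a 100%-identity block (fully ambiguous)."""
    design = syn.SyntheticDesign(
        n_species=3,
        genome_length_per_species=2000,
        genes_per_species=10,
        homology_blocks=[syn.HomologyBlock(("sp01", "sp02"), 0.3, 100.0)],
        seed=7,
    )
    return syn.generate_genomes(design)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
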