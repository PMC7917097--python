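import numpy as np
import pytest

from founderhap.simulate import (
    SimConfig,
    gene_drop_genomes,
    three_generation_design,
)


@pytest.fixture(scope="session")
def small_truth():
    """Error-free three-generation population, 3 chromosomes x 50 markers."""
    cfg = SimConfig(
        chromosomes=[(50, 60.0)] * 3,
        pedigree=three_generation_design(),
        seed=11,
    )
    return gene_drop_genomes(cfg)


@pytest.fixture(scope="session")
def noisy_truth():
    """Three-generation population with array-like error and missingness."""
    cfg = SimConfig(
        chromosomes=[(120, 60.0)] * 3,
        pedigree=three_generation_design(),
        genotype_error_rate=0.002,
        missing_rate=0.005,
        seed=13,
    )
    return gene_drop_genomes(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
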