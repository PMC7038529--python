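import numpy as np
import pytest

import gpbench as gp


@pytest.fixture(scope="session")
def small_genotypes() -> gp.GenotypeMatrix:
    """300 x 400 simulated panel, no missing calls, shared across tests."""
    return gp.simulate_genotypes(
        gp.GenotypeSimConfig(
            n_individuals=300, n_snps=400, n_chromosomes=4, missing_rate=0.0, seed=42
        )
    )


@pytest.fixture(scope="session")
def desk_genotypes() -> gp.GenotypeMatrix:
    """Desk-scale panel (n=2000, m=5000) used by the heavier checks."""
    return gp.simulate_genotypes(gp.GenotypeSimConfig(seed=2024))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
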