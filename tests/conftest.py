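import numpy as np
import pytest

from cherryblup import (
    GenotypeMatrix,
    KernelGBLUP,
    KernelSet,
    SimulationScenario,
    simulate_dataset,
    simulate_founders,
)


@pytest.fixture(scope="session")
def small_data():
    """A small full-structure dataset: 12 founders, 10 families of 5."""
    scenario = SimulationScenario(
        n_founders=12, n_families=10, offspring_per_family=5,
        n_markers=300, seed=7,
    )
    return simulate_dataset(scenario)


@pytest.fixture(scope="session")
def adi_fit(small_data):
    """Full ADI model fitted to the small dataset."""
    return KernelGBLUP().fit(small_data.phenotypes, small_data.kernels)


@pytest.fixture(scope="session")
def founder_kernels():
    """Unrelated founders and their kernel set (single-generation)."""
    founders = simulate_founders(40, 200, (0.2, 0.5), seed=11)
    return founders, KernelSet.from_genotypes(founders)


@pytest.fixture()
def random_dosage():
    """A complete polymorphic 6 x 20 dosage matrix."""
    rng = np.random.default_rng(99)
    while True:
        d = rng.integers(-1, 2, size=(6, 20)).astype(float)
        p = (d + 1.0).mean(axis=0) / 2.0
        if ((p > 0.0) & (p < 1.0)).all():
            break
    return GenotypeMatrix(
        ids=[f"i{k}" for k in range(6)],
        markers=[f"m{j}" for j in range(20)],
        dosage=d,
    )
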