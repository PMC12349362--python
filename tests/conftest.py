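import numpy as np
import pytest

from rugosity.expression import ExpressionMatrix
from rugosity.synthetic import (
    CountsConfig,
    PopulationConfig,
    WaveProfile,
    generate_counts,
    generate_population,
)


@pytest.fixture(scope="session")
def wavy_profile() -> WaveProfile:
    """Canonical noise-free sinusoid: a = 0.5 mm, lambda = 5 mm on a 30 mm section."""
    return WaveProfile(amplitude_mm=0.5, wavelength_mm=5.0)


@pytest.fixture(scope="session")
def default_population():
    return generate_population(PopulationConfig(seed=42))


@pytest.fixture(scope="session")
def planted_counts():
    """2000-gene matrix with 50 strong planted DE genes (log2FC 4, low dispersion)."""
    config = CountsConfig(n_genes=2000, n_de=50, log2fc_de=4.0, dispersion=0.02, seed=11)
    counts, lengths, truth = generate_counts(config)
    matrix = ExpressionMatrix(values=counts, gene_length_bp=lengths)
    return matrix, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
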