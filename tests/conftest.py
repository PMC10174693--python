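import numpy as np
import pytest

from doublering.model import CouplingParams, PopulationDensity


@pytest.fixture(scope="session")
def eta_samples():
    rng = np.random.default_rng(11)
    return rng.beta(2, 4, 400), rng.beta(2, 4, 400)


@pytest.fixture(scope="session")
def data_density(eta_samples):
    """Data-like density: chi = 2/3, skewed participation marginals."""
    return PopulationDensity(2 / 3, *eta_samples, n_eta=6, n_theta=48)


@pytest.fixture(scope="session")
def uniform_density():
    """Classic double-ring limit: eta_A = eta_B = 1."""
    return PopulationDensity.uniform_participation(2 / 3)


@pytest.fixture(scope="session")
def subcritical_couplings():
    return CouplingParams(j0=-0.5, js_A=0.8, js_B=2.0, j_a=0.2)
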