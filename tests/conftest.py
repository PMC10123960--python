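import numpy as np
import pytest

import specgwas as sg


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated trial shared across tests."""
    cfg = sg.SimConfig(n_lines=150, n_markers=400, n_bands=15,
                       pi_sparsity=0.97, seed=11)
    G = sg.simulate_genotypes(cfg)
    phenotypes, truth = sg.simulate_traits(G, cfg)
    spectra = sg.simulate_spectra(G, truth, cfg, phenotypes)
    return cfg, G, phenotypes, truth, spectra


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_dosages(rng):
    def make(n=100, m=50):
        return rng.integers(0, 3, size=(n, m)).astype(float)
    return make
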