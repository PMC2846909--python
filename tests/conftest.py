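import numpy as np
import pytest

from probgwas import simulate


@pytest.fixture(scope="session")
def family_data():
    """Small family sample with gene-dropped genotypes (shared, read-only)."""
    ped = simulate.simulate_pedigree(30, seed=42)
    freqs = simulate.draw_founder_freqs(2500, seed=43)
    G = simulate.gene_drop(ped, freqs, seed=44)
    return ped, freqs, G


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
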