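import numpy as np
import pandas as pd
import pytest

from ptrskit.datatypes import GenotypePanel
from ptrskit.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_ref=400, n_cohort=4000, n_blocks=8, block_size=10,
        n_tissues=2, genes_per_tissue=10, ld_rho=0.5, seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(123)


def make_panel(dosages, chrom="1", start=1, spacing=1000):
    """Panel with sequential positions and A/G variants."""
    dosages = np.asarray(dosages, float)
    n, m = dosages.shape
    variants = pd.DataFrame({
        "chrom": chrom,
        "pos": [start + j * spacing for j in range(m)],
        "id": [f"v{j}" for j in range(m)],
        "ref": "G",
        "alt": "A",
        "block": 0,
    })
    samples = np.array([f"s{i}" for i in range(n)])
    return GenotypePanel(samples, variants, dosages)
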