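import pytest
from hypothesis import settings

from tmtrollup.quantify import run_quant_pipeline

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from tmtrollup.synthetic_data import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A compact simulated TMT10 experiment (150 proteins, 4 WT vs 3 Cko)."""
    cfg = SimConfig(seed=5, n_proteins=150)
    psms, design, truth = simulate_dataset(cfg)
    return cfg, psms, design, truth


@pytest.fixture(scope="session")
def default_dataset():
    """The default-size simulated experiment (1000 proteins)."""
    cfg = SimConfig(seed=11, n_proteins=1000)
    psms, design, truth = simulate_dataset(cfg)
    return cfg, psms, design, truth


@pytest.fixture(scope="session")
def default_pipeline(default_dataset):
    """Normalized protein matrix + provenance for the default simulation."""
    _, psms, design, _ = default_dataset
    matrix, prov = run_quant_pipeline(psms, design)
    return matrix, prov
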