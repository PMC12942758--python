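import numpy as np
import pytest

from mirselect.spectral_data import Dataset, ReferenceTable, SpectrumSet, WavenumberGrid
from mirselect.synthetic_mir import SimConfig, simulate_dataset


@pytest.fixture
def toy_grid():
    return WavenumberGrid([4000.0, 3000.0, 2000.0, 1000.0, 500.0])


@pytest.fixture
def toy_spectra(toy_grid):
    rng = np.random.default_rng(42)
    return SpectrumSet(toy_grid, rng.normal(0.5, 0.1, (3, 5)), ("a", "b", "c"))


@pytest.fixture
def spxy_toy():
    """The 1-D three-sample dataset with hand-enumerable joint distances."""
    grid = WavenumberGrid([2.0, 1.0])
    X = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
    ids = ("s1", "s2", "s3")
    return Dataset(SpectrumSet(grid, X, ids),
                   ReferenceTable(ids, [0.0, 1.0, 4.0]))


@pytest.fixture(scope="session")
def small_sim():
    """A small corrupted synthetic dataset shared across tests."""
    return simulate_dataset(SimConfig(n=60, p=200, seed=7))


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-, scatter- and baseline-free synthetic data: exactly linear."""
    cfg = SimConfig(n=60, p=200, seed=7, noise_sd=0.0, scatter_slope_sd=0.0,
                    scatter_offset_sd=0.0, baseline_scale=0.0)
    return simulate_dataset(cfg)
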