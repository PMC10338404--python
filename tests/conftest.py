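import numpy as np
import pytest

from amadori import (
    SimulationConfig,
    load_default_library,
    load_random_coil_table,
    simulate_hsqc,
)
from amadori.simulate import EXAMPLE_SEQUENCE


@pytest.fixture(scope="session")
def library():
    return load_default_library()


@pytest.fixture(scope="session")
def coil_table():
    return load_random_coil_table()


@pytest.fixture(scope="session")
def example_sequence():
    return EXAMPLE_SEQUENCE


@pytest.fixture(scope="session")
def glycated_run(example_sequence):
    """Noiseless default-grid simulation at G = 2 (shared across tests)."""
    config = SimulationConfig(sequence=example_sequence, glycations_per_molecule=2.0)
    spectrum, truth = simulate_hsqc(config)
    return config, spectrum, truth


@pytest.fixture()
def single_gaussian_spectrum():
    """One unit-amplitude Gaussian (sigma_C=0.05, sigma_H=0.005) on a fine grid."""
    from amadori.spectra import GriddedSpectrum2D

    c = 40 + 0.0125 * np.arange(321)
    h = 3 + 0.00125 * np.arange(321)
    cg, hg = np.meshgrid(c, h, indexing="ij")
    intensity = np.exp(-0.5 * ((cg - 42) / 0.05) ** 2 - 0.5 * ((hg - 3.2) / 0.005) ** 2)
    return GriddedSpectrum2D(intensity, c, h)
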