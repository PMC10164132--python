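import numpy as np
import pytest

from scdemux import PrimerSet, SimConfig, simulate_library


@pytest.fixture(scope="session")
def primers() -> PrimerSet:
    return PrimerSet()


@pytest.fixture(scope="session")
def clean_lib():
    """Small error-free library: every unit must be exactly recoverable."""
    cfg = SimConfig(
        n_reads=120, seed=11, sub_rate=0.0, ins_rate=0.0, del_rate=0.0,
        n_cells=40, whitelist_size=120, spike_in_fraction=0.0,
    )
    return simulate_library(cfg)


@pytest.fixture(scope="session")
def noisy_lib():
    """Small library at the default (realistic) error rates."""
    cfg = SimConfig(n_reads=150, seed=5, n_cells=40, whitelist_size=150)
    return simulate_library(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
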