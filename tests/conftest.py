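import numpy as np
import pytest

from calwave import (DynamicsParams, KineticParams, Kymograph,
                     SimulationConfig, run_simulation)


@pytest.fixture
def kinetics() -> KineticParams:
    """Standard kinetic parameter set."""
    return KineticParams()


@pytest.fixture
def dynamics() -> DynamicsParams:
    """Standard dynamic parameter set (p_hat = 1.6 uM/s)."""
    return DynamicsParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_run():
    """One deterministic 1.5 s simulation shared across tests."""
    cfg = SimulationConfig(seed=7, duration=1.5)
    kymo, summary = run_simulation(cfg)
    return cfg, kymo, summary


def make_kymograph(pixels, record_max=3.2, dx_pixel=0.18, dt_row=0.0375):
    return Kymograph(pixels=np.asarray(pixels, dtype=np.uint8),
                     dx_pixel=dx_pixel, dt_row=dt_row, record_max=record_max)
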