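import numpy as np
import pytest

from aortamech.datasets import MembraneParams, RunConfig, load_fixture_tables
from aortamech.membrane import synthetic_series
from aortamech.thickwall import pressure_sweep


@pytest.fixture(scope="session")
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def tables():
    return load_fixture_tables()


@pytest.fixture(scope="session")
def arteries(tables):
    return {a.set_id: a for a in tables[0]}


@pytest.fixture(scope="session")
def membranes(tables):
    return {m.set_id: m for m in tables[1]}


@pytest.fixture(scope="session")
def sweeps(arteries, config):
    """Solved pressure sweeps for every packaged set (shared; expensive)."""
    return {sid: pressure_sweep(a, config) for sid, a in arteries.items()}


@pytest.fixture(scope="session")
def membrane_truth() -> MembraneParams:
    """A healthy-aorta-like membrane parameter vector used as ground truth."""
    return MembraneParams(set_id="truth", Ri=5.2, c=13.64, k1=41.97,
                          k2=3.25, beta=41.43, lam=1.0918, Fred_est=0.58)


@pytest.fixture(scope="session")
def membrane_series(membrane_truth, config):
    """Noise-free pressure-radius signal of an exact membrane artery."""
    return synthetic_series(membrane_truth, config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
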