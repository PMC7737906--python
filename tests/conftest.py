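import numpy as np
import pytest

from omnigene.io_ld import LDProvider
from omnigene.simulate import build_locus, generate_fixture_panel


def ar1(m: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix, the standard LD stand-in for small tests."""
    idx = np.arange(m)
    return rho ** np.abs(np.subtract.outer(idx, idx))


def exchangeable(m: int, rho: float) -> np.ndarray:
    return (1 - rho) * np.eye(m) + rho * np.ones((m, m))


@pytest.fixture(scope="session")
def fixture_set():
    """Small synthetic panel + annotations shared across the suite."""
    return generate_fixture_panel(seed=1, n_genes=6)


@pytest.fixture(scope="session")
def locus(fixture_set):
    return build_locus("G003", fixture_set)


@pytest.fixture(scope="session")
def ld_provider(fixture_set):
    return LDProvider(fixture_set.panel)
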