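import numpy as np
import pytest

from segdupcnv import simulate_paralog_pair
from segdupcnv.cohort import default_hotspots, default_probe_design


@pytest.fixture(scope="session")
def small_pair():
    """2-kb paralog pair at 1% divergence (20 PSVs)."""
    return simulate_paralog_pair(2000, 0.01, seed=7)


@pytest.fixture(scope="session")
def locus_pair():
    """Full-scale 16-kb pair at 1.5% divergence (240 PSVs)."""
    return simulate_paralog_pair(16_000, 0.015, seed=1)


@pytest.fixture(scope="session")
def hotspots():
    return default_hotspots(16_000)


@pytest.fixture(scope="session")
def probes():
    return default_probe_design(16_000)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
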