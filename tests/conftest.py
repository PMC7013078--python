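import datetime as dt

import pytest
from hypothesis import settings

from oncotrigger import SimConfig, analyze_bundle, default_codebook, simulate

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


def d(iso: str) -> dt.date:
    return dt.date.fromisoformat(iso)


@pytest.fixture(scope="session")
def book():
    return default_codebook()


@pytest.fixture(scope="session")
def sim500():
    """A 500-patient synthetic bundle with ground truth (fixed seed)."""
    return simulate(SimConfig(n_patients=500, seed=1))


@pytest.fixture(scope="session")
def analyzed500(sim500):
    bundle, _ = sim500
    return analyze_bundle(bundle)


@pytest.fixture(scope="session")
def sim_large():
    """Larger bundle for composition-frequency checks (fixed seed)."""
    return simulate(SimConfig(n_patients=5000, seed=11))


@pytest.fixture(scope="session")
def analyzed_large(sim_large):
    bundle, _ = sim_large
    return analyze_bundle(bundle)
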