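import numpy as np
import pytest

from m6avar.synthetic_data import SimConfig, simulate_study

# compact study conditions for unit tests: same structure as the defaults,
# scaled down so the whole suite stays fast
SMALL = dict(
    n_chroms=2,
    chrom_length=120_000,
    n_transcripts=70,
    n_peaks=180,
    n_lead_snps=60,
)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=101, **SMALL)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def default_study():
    """One study at the default (full-size) conditions."""
    return simulate_study(SimConfig(seed=202))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
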