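import warnings

import pytest

from methcompare import SimulationConfig, generate_dataset
from methcompare.pipeline import _primary_beta


@pytest.fixture(scope="session")
def small_dataset():
    """Default study design at reduced probe count."""
    return generate_dataset(SimulationConfig(n_cpg=300, seed=1))


@pytest.fixture(scope="session")
def noise_free_dataset():
    """No technical noise, no array offsets, no corrupted SNP probes."""
    return generate_dataset(SimulationConfig(
        n_cpg=300, seed=2, noise_sd=0.0, array_bias_sd=0.0,
        n_corrupt_snp_probes=0))


@pytest.fixture(autouse=True)
def _quiet_tie_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="tied best match")
        yield


@pytest.fixture
def primary_beta():
    """Helper: donor-level beta matrix (replicates dropped, base probe ids)."""
    return _primary_beta
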