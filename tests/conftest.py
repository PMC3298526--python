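import numpy as np
import pytest

from pathstrat import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down cohort for fast end-to-end unit tests."""
    return CohortConfig(
        n_genes=40, n_samples_per_dataset=(80, 60), n_pathways=5,
        pathway_size_range=(6, 10), driver_pathway_size=12, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
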