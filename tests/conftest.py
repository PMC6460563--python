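import numpy as np
import pytest

from xskew import CohortConfig, generate_cohort, run_pipeline_from_data


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-trio default-parameter cohort shared across tests."""
    return generate_cohort(CohortConfig(n_trios=20, seed=1))


@pytest.fixture(scope="session")
def small_result(small_cohort):
    c = small_cohort
    return run_pipeline_from_data(c.genotypes, c.counts, c.exons, c.par, c.trios)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
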