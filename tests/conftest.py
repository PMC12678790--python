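import numpy as np
import pytest

from methgrad import meth_io, synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort (12 sites/pattern) shared across unit tests."""
    cfg = synthetic.SyntheticCohortConfig(sites_per_pattern=12, seed=7)
    cells, truth = synthetic.generate_methylation_cohort(cfg)
    cohort = meth_io.assemble_cohort(synthetic.cohort_to_sample_tables(cells))
    return cfg, cells, truth, cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
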