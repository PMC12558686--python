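import numpy as np
import pytest

import msmediation as mm


@pytest.fixture(scope="session")
def small_cohort():
    """A mid-sized default cohort shared by read-only tests."""
    return mm.generate_cohort(mm.default_params(n_subjects=4000, seed=20240901))


@pytest.fixture(scope="session")
def coded_wide(small_cohort):
    """Eligible + coded wide table from the shared cohort."""
    eligible = mm.apply_eligibility(small_cohort).cohort
    return mm.code_cohort(eligible).df


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
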