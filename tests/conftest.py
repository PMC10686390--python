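import numpy as np
import pytest

import mpsf


@pytest.fixture(scope="session")
def geometry():
    return mpsf.ScanGeometry()


@pytest.fixture(scope="session")
def grid():
    return mpsf.generate_default_grid()


@pytest.fixture(scope="session")
def quant():
    return mpsf.QuantConfig()


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small cohort reused across tests: 4 patients, 6 eyes, 2 visits."""
    cfg = mpsf.CohortConfig(n_patients=4, n_eyes=6, n_visits=2)
    return mpsf.simulate_cohort(cfg, 7)


@pytest.fixture(scope="session")
def tiny_table(tiny_bundle):
    return mpsf.extract_cohort_table(tiny_bundle)


@pytest.fixture(scope="session")
def medium_bundle():
    """Mid-size longitudinal cohort for model-fitting tests."""
    cfg = mpsf.CohortConfig(n_patients=12, n_eyes=18, n_visits=5)
    return mpsf.simulate_cohort(cfg, 11)


@pytest.fixture(scope="session")
def medium_table(medium_bundle):
    return mpsf.extract_cohort_table(medium_bundle)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
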