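import numpy as np
import pytest

from ppsp import cohort as cohort_mod


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A study-sized synthetic cohort without missingness, fixed seed."""
    cfg = cohort_mod.default_config()
    cfg.missingness_rates = {}
    return cohort_mod.generate_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    """A study-sized synthetic cohort with the default MCAR missingness."""
    return cohort_mod.generate_cohort(cohort_mod.default_config(), seed=11)
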