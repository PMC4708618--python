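import pytest

from spillover_cea import reference_care_packages, reference_scenario
from spillover_cea.synthetic_cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def reference_menu():
    """The six-package worked-example funding menu."""
    return reference_care_packages()


@pytest.fixture(scope="session")
def full_info_scenario():
    """Full-information scenario: both carers recognized."""
    return reference_scenario(2)


@pytest.fixture(scope="session")
def noisy_cohort():
    """A moderately sized cohort with noise, shared across estimation tests."""
    return generate_cohort(CohortSpec(n_dyads=500, seed=20260921, noise_sd=0.1))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Zero-noise cohort: utilities equal the linear predictor exactly."""
    return generate_cohort(CohortSpec(n_dyads=120, seed=7, noise_sd=0.0))
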