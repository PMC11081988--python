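import numpy as np
import pytest

from pmmetab.simulate import (CohortConfig, KineticModel, generate_cohort,
                              stable_kinetics)


@pytest.fixture(scope="session")
def noise_free_stable_cohort():
    """Small cohort with no drift and no noise of any kind."""
    kin = {
        f"a{i}": KineticModel(
            "stable", sigma_inter=0.0, sigma_intra=0.0,
            baseline_log_mean=10.0 + 0.2 * i,
        )
        for i in range(5)
    }
    config = CohortConfig(n_cases=30, seed=7, sigma_batch=0.0, sigma_prep=0.0)
    return generate_cohort(config, kin)


@pytest.fixture(scope="session")
def noisy_stable_cohort():
    """Default-noise cohort with stable kinetics (null drift)."""
    config = CohortConfig(n_cases=60, seed=11)
    return generate_cohort(config, stable_kinetics(4))


@pytest.fixture(scope="session")
def drift_cohort():
    """Noise-free cohort with one doubling analyte and one stable analyte."""
    kin = {
        "riser": KineticModel(
            "steady_increase", rate=1.0 / 71.0, sigma_inter=0.0, sigma_intra=0.0
        ),
        "flat": KineticModel("stable", sigma_inter=0.0, sigma_intra=0.0),
    }
    config = CohortConfig(n_cases=50, seed=3, sigma_batch=0.2, sigma_prep=0.0)
    return generate_cohort(config, kin)
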