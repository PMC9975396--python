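import dataclasses

import numpy as np
import pytest

import fcnorm
from fcnorm.simulate import CohortConfig


@pytest.fixture(scope="session")
def atlas():
    return fcnorm.DEFAULT_ATLAS


@pytest.fixture(scope="session")
def small_cohort_config():
    """A reduced cohort used by fast structural tests."""
    full = fcnorm.default_config(seed=7)
    return dataclasses.replace(
        full,
        n_per_group={"H-Train": 60, "H-Test-U": 15, "SCZ-Test-U": 15},
        perturbations={"SCZ-Test-U": full.perturbations["SCZ-Test-U"]},
    )


@pytest.fixture(scope="session")
def small_cohort(small_cohort_config):
    return fcnorm.generate_cohort(small_cohort_config)


@pytest.fixture(scope="session")
def small_report(small_cohort_config):
    """One small but complete pipeline run shared across tests."""
    cfg = fcnorm.RunConfig(
        cohort=small_cohort_config,
        model=fcnorm.AutoencoderSpec(epochs=200),
        seed=7,
    )
    return fcnorm.run_pipeline(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
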