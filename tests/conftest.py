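import numpy as np
import pytest

import isotemporal as it
from isotemporal.coda import PART_NAMES


@pytest.fixture(scope="session")
def centre() -> it.Composition:
    """The published compositional mean, already closed to 1440 min."""
    return it.close(it.DEFAULT_CENTRE)


@pytest.fixture(scope="session")
def default_profile() -> it.CovariateProfile:
    return it.CovariateProfile(sex="female", age=12.0)


@pytest.fixture(scope="session")
def small_study():
    """A zero-free synthetic cohort (n=400) with its ground truth."""
    cfg = it.GeneratorConfig(n=400, zero_rate=0.0)
    data, truth = it.generate_dataset(cfg, seed=20240917)
    return cfg, data, truth


@pytest.fixture(scope="session")
def psych_model(small_study):
    cfg, data, _ = small_study
    return it.fit_outcome_model(
        data[list(PART_NAMES)], data, data["psychosocial"], "psychosocial")


@pytest.fixture(scope="session")
def bodyfat_model(small_study):
    cfg, data, _ = small_study
    return it.fit_outcome_model(
        data[list(PART_NAMES)], data, data["bodyfat"], "bodyfat",
        transform="log")
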