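import numpy as np
import pytest

from liverfat import CohortConfig, ModelConstants, generate_cohort


@pytest.fixture(scope="session")
def constants() -> ModelConstants:
    return ModelConstants()


@pytest.fixture(scope="session")
def small_cohort(constants):
    """30 patients, fixed seed — shared across read-only tests."""
    return generate_cohort(CohortConfig(n_patients=30, seed=42), constants)


@pytest.fixture(scope="session")
def fatty_patient(constants):
    """The highest-PDFF patient of a fixed cohort, for recovery tests."""
    records = generate_cohort(CohortConfig(n_patients=60, seed=11), constants)
    return max(records, key=lambda r: r.true_pdff)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
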