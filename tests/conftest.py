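import pytest

from modcare import DemographicConfig, generate_cohort
from modcare import reference


@pytest.fixture(scope="session")
def study_coeffs():
    return reference.study_coefficients()


@pytest.fixture(scope="session")
def study_truth():
    return reference.study_truth(noise_sd=0.6)


@pytest.fixture(scope="session")
def small_cohort(study_truth):
    """A 60-respondent cohort with the study marginals and effects."""
    return generate_cohort(DemographicConfig(n=60, seed=7), study_truth)


@pytest.fixture(scope="session")
def medium_cohort(study_truth):
    """A 400-respondent cohort, big enough for screening and regression."""
    return generate_cohort(DemographicConfig(n=400, seed=21), study_truth)
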