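import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gvhdtte as g

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params() -> g.FinalModelParameters:
    """Reference estimates of the final transit-delay model."""
    return g.FinalModelParameters()


@pytest.fixture(scope="session")
def neutral_params(params) -> g.FinalModelParameters:
    """Transit base model with every covariate effect switched off."""
    return params.replace(
        gamma_wbc=0.0, lam_mrd=1.0, lam_sex=1.0, lam_flu=1.0,
        gamma_age=0.0, slope_csa=0.0,
    )


def constant_patient_trajectory(
    params,
    csa: float = 250.0,
    age: float = 54.0,
    related: bool = False,
    mrd: bool = False,
    f2m: bool = False,
    flutbi: bool = False,
    step: float = 0.1,
) -> g.HazardTrajectory:
    """Trajectory of a patient with constant CsA and WBC at the median."""
    static = g.StaticCovariates(
        "p0", age, donor_related=related, matched_related_donor=mrd,
        female_to_male=f2m, flutbi=flutbi,
    )
    return g.hazard_trajectory(
        static,
        g.LongitudinalCovariate.constant("p0", 1.0),
        g.LongitudinalCovariate.constant("p0", csa),
        g.PopulationReference.constant(1.0),
        params,
        step=step,
    )


@pytest.fixture(scope="session")
def reference_trajectory(params) -> g.HazardTrajectory:
    return constant_patient_trajectory(params)


@pytest.fixture(scope="session")
def small_cohort() -> g.CohortDataset:
    """Default-condition synthetic cohort, small enough for fast tests."""
    return g.generate_cohort(g.GeneratorConfig(n_patients=150, seed=11))


@pytest.fixture(scope="session")
def medium_cohort() -> g.CohortDataset:
    return g.generate_cohort(g.GeneratorConfig(n_patients=1000, seed=23))
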