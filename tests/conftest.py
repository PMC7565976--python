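import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from tumornlme import PopulationParams, StudyDesign, simulate_cohort


@pytest.fixture(scope="session")
def printed_pop():
    """Published population values of the antagonist study."""
    return PopulationParams()


@pytest.fixture(scope="session")
def small_cohort(printed_pop):
    """A compact three-arm cohort reused by fast structural tests."""
    design = StudyDesign(n_per_arm=4, seed=42)
    return simulate_cohort(design, printed_pop)


@pytest.fixture(scope="session")
def dense_vehicle_cohort():
    """Densely observed vehicle-only cohort with mild noise: rich data for
    which estimators should be nearly exact."""
    pop = PopulationParams(
        k_growth_mean=0.64, omega_k=0.2, v_max_mean=1620.0, omega_vmax=0.2,
        eff_mean=0.52, omega_eff=0.2, gamma=0.17,
        sigma_prop=0.05, sigma_add=1.0,
    )
    design = StudyDesign(
        arms=("vehicle",), n_per_arm=12,
        obs_times=tuple(np.arange(0.0, 10.1, 1.0)), study_end=10.0, seed=7,
    )
    return simulate_cohort(design, pop)[0], pop
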