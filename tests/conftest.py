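import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def small_cf_cohort():
    """Fully observed single-rater cohort from the reference component
    matrices, shared across tests that only read it."""
    from twinwell import scenarios
    from twinwell.datatypes import SimulationConfig
    from twinwell.synthetic_data import simulate_twin_cohort

    config = SimulationConfig(
        n_mz_pairs=800,
        n_dz_pairs=800,
        seed=101,
        cf_params=scenarios.reference_cf_params(),
    )
    return simulate_twin_cohort(config)


@pytest.fixture(scope="session")
def multirater_cohort():
    """Dual-rater cohort at the period-wise psychometric calibrations."""
    from twinwell import scenarios
    from twinwell.datatypes import SimulationConfig
    from twinwell.synthetic_data import simulate_twin_cohort

    config = SimulationConfig(
        n_mz_pairs=1500,
        n_dz_pairs=1500,
        seed=202,
        multirater_by_period=scenarios.MULTIRATER_BY_PERIOD,
    )
    return simulate_twin_cohort(config)
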