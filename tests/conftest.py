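import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from placecode1d import AnalysisConfig, CohortSpec, make_grid, simulate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def grid57():
    return make_grid(170.0, 3.0)


@pytest.fixture(scope="session")
def small_cohort():
    """One animal, few cells/laps: cheap but passes through every stage."""
    spec = CohortSpec(n_animals=1, n_cells=8, n_laps=10, seed=7)
    sessions, truth = simulate_cohort(spec)
    return spec, sessions, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
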