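import numpy as np
import pytest

from pufval import SimulationConfig, simulate_cohort, uniform_puf
from pufval.puf import PersonalUtilityFunction
from pufval.state_space import DIMENSIONS


def random_puf(rng: np.random.Generator) -> PersonalUtilityFunction:
    """A random valid PUF: Dirichlet weights, uniform level-2 fractions."""
    w = rng.dirichlet(np.full(5, 2.0))
    frac = rng.uniform(0, 1, 5)
    return PersonalUtilityFunction(
        weight=dict(zip(DIMENSIONS, map(float, w))),
        level2_fraction=dict(zip(DIMENSIONS, map(float, frac))),
    )


@pytest.fixture(scope="session")
def random_pufs():
    rng = np.random.default_rng(20231205)
    return [random_puf(rng)] + [random_puf(rng) for _ in range(19)]


@pytest.fixture
def equal_puf():
    return uniform_puf()


@pytest.fixture(scope="session")
def noise_free_cohort():
    """n=50 noise-free, rounding off: stated responses reveal latents exactly."""
    config = SimulationConfig(
        n_respondents=50, seed=11, choice_noise_scale=0.0, rating_rounding=0.0
    )
    latents, records = simulate_cohort(config)
    return config, latents, records


@pytest.fixture(scope="session")
def realistic_cohort():
    """n=60 with round-number bias (grid 5) and logistic choice noise 0.05."""
    config = SimulationConfig(
        n_respondents=60, seed=11, choice_noise_scale=0.05, rating_rounding=5.0
    )
    latents, records = simulate_cohort(config)
    return config, latents, records
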