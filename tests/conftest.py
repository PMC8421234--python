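import numpy as np
import pytest

from thyntcp import CohortSimConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20210823)


@pytest.fixture(scope="session")
def cohort_small():
    """A study-sized synthetic cohort (n = 69)."""
    return simulate_cohort(CohortSimConfig(n_patients=69, seed=11))


@pytest.fixture(scope="session")
def cohort_large():
    """A large synthetic cohort for asymptotic checks."""
    return simulate_cohort(CohortSimConfig(n_patients=2000, seed=42))


def random_grid_and_mask(rng, max_side=12, max_dose=80.0):
    """Random dose grid + non-empty random mask (shared test helper)."""
    shape = tuple(int(s) for s in rng.integers(2, max_side + 1, size=3))
    values = rng.uniform(0.0, max_dose, size=shape)
    mask = rng.random(shape) < rng.uniform(0.2, 0.8)
    if not mask.any():
        mask.flat[int(rng.integers(mask.size))] = True
    spacing = tuple(rng.uniform(0.5, 3.0, size=3))
    return values, mask, spacing
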