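import numpy as np
import pytest

from fcident import SyntheticSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_cohort():
    """8 subjects x 2 visits x 12 regions, moderate noise."""
    spec = SyntheticSpec(n_subjects=8, n_regions=12, seed=42)
    stack, truth = generate_cohort(spec)
    return stack, truth


def random_symmetric_fc(rng, n):
    a = rng.uniform(-0.9, 0.9, size=(n, n))
    m = 0.5 * (a + a.T)
    np.fill_diagonal(m, 1.0)
    return m
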