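import numpy as np
import pytest

from rildseg import phantom


@pytest.fixture(scope="session")
def small_cohort():
    """Two patients x five time points on compact grids."""
    spec = phantom.PhantomSpec(n_patients=2, grid_shape=(16, 32, 48), seed=7)
    cases, manifest = phantom.generate_cohort(spec)
    return cases, manifest


@pytest.fixture(scope="session")
def one_case(small_cohort):
    cases, _ = small_cohort
    return cases[3]


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_label_volume(rng, shape=(6, 10, 12)):
    """Random lung mask + label map pair for metric/filter oracles."""
    mask = rng.random(shape) < 0.6
    labels = np.where(mask, rng.integers(1, 6, shape), 0).astype(np.int16)
    return labels, mask
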