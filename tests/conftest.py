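import numpy as np
import pytest
from hypothesis import settings

from netage import CohortSpec, make_cohort, make_masks

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_masks():
    return make_masks((16, 16, 16), 2, seed=1)


@pytest.fixture(scope="session")
def small_cohort(small_masks):
    """60 subjects on a 16^3 grid, one strong and one weak network."""
    spec = CohortSpec(
        n_subjects=60,
        grid_dims=(16, 16, 16),
        n_networks=2,
        target_r=(-0.8, -0.4),
        seed=7,
    )
    subjects, table = make_cohort(spec, small_masks)
    return spec, subjects, table
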