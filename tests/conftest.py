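import numpy as np
import pytest

from neohrv.synthetic import (
    SyntheticCohortSpec,
    default_group_profiles,
    generate_cohort,
    generate_rr_series,
)


@pytest.fixture(scope="session")
def mild_profile():
    return default_group_profiles()[0]


@pytest.fixture(scope="session")
def severe_profile():
    return default_group_profiles()[1]


@pytest.fixture(scope="session")
def clean_rr():
    """Noiseless constant 500 ms series covering 600 s (1200 beats)."""
    from neohrv.synthetic import GroupProfile

    profile = GroupProfile(label=0, mean_nn_ms=500.0)
    return generate_rr_series(profile, 600.0, seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """Shared small contrasted cohort (8/group, 10-min epochs)."""
    spec = SyntheticCohortSpec(n_per_group=8, epoch_duration_s=600.0, seed=123)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
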