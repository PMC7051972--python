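import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def censored_outcomes(rng):
    """A generic censored sample: exponential events, exponential censoring."""
    n = 80
    t_event = rng.exponential(30.0, n)
    t_cens = rng.exponential(60.0, n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event


@pytest.fixture
def small_cohort():
    from survscale.synthetic import CohortConfig, generate_cohort

    return generate_cohort(
        CohortConfig(
            n_subjects=120,
            n_binary_features=4,
            n_continuous_features=3,
            n_noise_features=2,
            group_separation=2.0,
            missing_rate=0.1,
            seed=7,
        )
    )
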