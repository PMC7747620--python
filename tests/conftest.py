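import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_expression() -> pd.DataFrame:
    """3 features x 4 samples."""
    return pd.DataFrame(
        [[5.0, 1.0, 3.0, 4.0],
         [1.0, 2.0, 2.0, 9.0],
         [2.5, 2.5, 2.5, 7.0]],
        index=["m1", "m2", "m3"],
        columns=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture
def small_clinical() -> pd.DataFrame:
    clin = pd.DataFrame(
        {"time": [100.0, 200.0, 300.0, 400.0],
         "event": [1, 1, 0, 1]},
        index=["s1", "s2", "s3", "s4"],
    )
    clin.index.name = "sample_id"
    return clin


@pytest.fixture
def survival_cohort():
    """A 40-subject two-group cohort with a real group effect and censoring."""
    rng = np.random.default_rng(7)
    n = 40
    groups = np.arange(n) % 2 == 0
    lam = np.where(groups, 2.0, 1.0) / 100.0
    t_event = rng.exponential(1.0 / lam)
    t_cens = rng.uniform(0, 250, n)
    times = np.minimum(t_event, t_cens)
    events = (t_event <= t_cens).astype(int)
    return times, events, groups
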