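import numpy as np
import pandas as pd
import pytest

from survsim_qba import (
    BenzoLikeSpec,
    Cohort,
    ColonLikeSpec,
    OutcomePool,
    make_benzo_like,
    make_colon_like,
)


@pytest.fixture(scope="session")
def colon_data():
    """Full-scale colon-like cohort (n=906), shared across tests."""
    return make_colon_like(ColonLikeSpec(), np.random.default_rng(7))


@pytest.fixture(scope="session")
def colon_small():
    """Small colon-like cohort for fast pipeline tests."""
    return make_colon_like(ColonLikeSpec(n=150), np.random.default_rng(11))


@pytest.fixture(scope="session")
def benzo_small():
    """Small drug cohort (n=120, <=1.5y) for fast TVE pipeline tests."""
    spec = BenzoLikeSpec(n=120, max_follow_up_days=540)
    return make_benzo_like(spec, np.random.default_rng(13))


@pytest.fixture
def toy_cohort():
    """Five subjects with distinct covariate patterns."""
    cov = pd.DataFrame({"z": [0.0, 1.0, -1.0, 0.5, 2.0]})
    return Cohort(
        ids=np.arange(5),
        exposure=np.array([1, 0, 1, 0, 0]),
        covariates=cov,
    )


@pytest.fixture
def toy_pool():
    return OutcomePool(
        event_times=np.array([3.0, 5.0, 8.0]),
        censoring_times=np.array([6.0, 9.0]),
    )


@pytest.fixture
def worked_example_frame():
    """Four subjects whose Cox exposure coefficient is exactly log(2)/2."""
    return pd.DataFrame(
        {
            "exposure": [1, 0, 1, 0],
            "time": [1.0, 2.0, 3.0, 3.0],
            "status": [1, 1, 0, 0],
        }
    )
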