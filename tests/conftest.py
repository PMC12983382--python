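import warnings

import numpy as np
import pytest

from bgrisk.synthetic import SyntheticParams, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(SyntheticParams(seed=11))


@pytest.fixture(scope="session")
def null_cohorts():
    """500 replicate cohorts under the null (hazard independent of score).

    Shared by the calibration checks; seeds 0..499.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [
            generate_cohort(SyntheticParams(seed=i, hazard_ratio_per_point=1.0))
            for i in range(500)
        ]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
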