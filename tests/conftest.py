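import numpy as np
import pytest

from isokin.bodywater import BodyWaterCurve
from isokin.datasets import OPTIMAL_TIMES, WEEKLY_TIMES, sample_precursor_target_params


@pytest.fixture(scope="session")
def curve():
    return BodyWaterCurve()


@pytest.fixture(scope="session")
def daily_times():
    return OPTIMAL_TIMES


@pytest.fixture(scope="session")
def weekly_times():
    return WEEKLY_TIMES


@pytest.fixture(scope="session")
def pt_ensemble():
    """Small fixed ensemble of precursor/target parameter draws."""
    return sample_precursor_target_params(12, seed=20240901)
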