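import numpy as np
import pytest

from nirscog.synthetic import default_effect_config, make_cohort
from nirscog.types import BlockSchedule


@pytest.fixture(scope="session")
def default_schedule() -> BlockSchedule:
    return BlockSchedule.alternating()


@pytest.fixture(scope="session")
def small_cohort():
    """A 24-participant cohort with the shipped effect configuration."""
    participants, amplitudes = make_cohort(12, default_effect_config(), seed=7)
    return participants, amplitudes


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
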