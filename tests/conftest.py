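import numpy as np
import pytest

from magpulse import CohortConfig, custom_2021, mp09_2020


@pytest.fixture
def circuit_2020():
    """First-generation treatment circuit (270 uF bank, ramp shut-off)."""
    return mp09_2020("treatment")


@pytest.fixture
def circuit_2020_sham():
    return mp09_2020("sham")


@pytest.fixture
def circuit_2021():
    """Second-generation treatment circuit (940 uF bank, flyback)."""
    return custom_2021("treatment")


@pytest.fixture
def rng():
    return np.random.default_rng(20230745)


@pytest.fixture
def small_cohort_config():
    """Null cohort small enough for fast battery runs."""
    return CohortConfig.default(n_per_cell=10)
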