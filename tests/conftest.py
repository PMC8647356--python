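import dataclasses

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

from asthmacea.mortality import LifeTable, synthetic_life_table
from asthmacea.parameters import base_case_parameters


@pytest.fixture
def base_params():
    return base_case_parameters()


@pytest.fixture(scope="session")
def life_table():
    return synthetic_life_table(0, 100)


@pytest.fixture(scope="session")
def no_mortality_table():
    """Zero mortality at all ages except the forced terminal year."""
    ages = np.arange(0, 101)
    qx = np.zeros(ages.size)
    qx[-1] = 1.0
    return LifeTable(ages, qx)


def with_settings(params, **overrides):
    """Copy of a parameter set with settings fields replaced."""
    return dataclasses.replace(
        params, settings=dataclasses.replace(params.settings, **overrides))


@pytest.fixture
def short_params(base_params):
    """Base case truncated to a 10-year horizon for fast model runs."""
    return with_settings(base_params, horizon_age_years=40)
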