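import numpy as np
import pandas as pd
import pytest

from sonoseed.design import build_l16, default_factors
from sonoseed.synthetic_data import (
    LayoutConfig,
    fixture_effects,
    gen_germination,
    gen_seedling_lengths,
    load_fixture_means,
)


@pytest.fixture(scope="session")
def design():
    return build_l16()


@pytest.fixture(scope="session")
def factors():
    return default_factors()


@pytest.fixture(scope="session")
def fixture_means():
    return load_fixture_means()


@pytest.fixture(scope="session")
def effects():
    return fixture_effects()


@pytest.fixture(scope="session")
def dish_data(design, effects):
    return gen_germination(design, LayoutConfig(), effects, seed=20260905)


@pytest.fixture(scope="session")
def seedling_data(design, effects, dish_data):
    return gen_seedling_lengths(dish_data, effects, seed=20260906)
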