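import numpy as np
import pytest

from airtrace import synthetic_city as sc
from airtrace.concentration import ConcentrationField, GridSpec
from airtrace.diary import PersonDay, Trip


@pytest.fixture(scope="session")
def city_config():
    """Default synthetic study area at a reduced household count."""
    return sc.CityConfig(seed=7, n_households=120)


@pytest.fixture(scope="session")
def network(city_config):
    return sc.generate_network(city_config)


@pytest.fixture(scope="session")
def field(city_config, network):
    return sc.generate_field(city_config, network)


@pytest.fixture(scope="session")
def population(city_config, network, field):
    return sc.generate_population(city_config, network, field)


@pytest.fixture
def uniform_field():
    """3x3 km field, constant 10 μg/m³ at every cell and hour."""
    grid = GridSpec(0.0, 0.0, 1000.0, 3, 3)
    return ConcentrationField(grid, np.full((24, 3, 3), 10.0))


def make_person(trips=None, residence=(0.0, 0.0), **overrides):
    """A valid single person-day for hand-constructed scenarios."""
    kwargs = dict(
        person_id="p0",
        household_id="h0",
        age_group="19-45",
        black=False,
        hispanic=False,
        white=True,
        asian=False,
        income_category="middle",
        gender="female",
        residence_urbanicity="suburban",
        residence=residence,
        trips=trips or [],
    )
    kwargs.update(overrides)
    return PersonDay(**kwargs)


def round_trip_person(residence=(0.0, 0.0), work=(2000.0, 0.0)):
    """Leave 480, 30-min travel, 480-min work dwell, 30-min travel home."""
    return make_person(
        residence=residence,
        trips=[
            Trip(residence, work, 480.0, 30.0, 480.0, "work"),
            Trip(work, residence, 990.0, 30.0, 420.0, "home"),
        ],
    )
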