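import numpy as np
import pytest

from kermalab import (DEFAULT_GRID, EnvironmentalConditions,
                      air_density_ideal, build_response_matrix,
                      chamber_preset, load_coefficient_table)
from kermalab.synthetic import default_spectrum


@pytest.fixture(scope="session")
def air_table():
    return load_coefficient_table("dry_air", "renormalized")


@pytest.fixture(scope="session")
def air_table_unren():
    return load_coefficient_table("dry_air", "unrenormalized")


@pytest.fixture(scope="session")
def water_table():
    return load_coefficient_table("water_vapor", "renormalized")


@pytest.fixture(scope="session")
def ge_table():
    return load_coefficient_table("germanium", "renormalized")


@pytest.fixture(scope="session")
def response(ge_table):
    return build_response_matrix(DEFAULT_GRID, ge_table)


@pytest.fixture(scope="session")
def spectrum_default(air_table):
    return default_spectrum(air_table=air_table)


@pytest.fixture(scope="session")
def lamperti():
    return chamber_preset("lamperti")


@pytest.fixture(scope="session")
def ritz():
    return chamber_preset("ritz")


@pytest.fixture(scope="session")
def rho_ref():
    """Dry-air density at reference conditions, g/cm^3."""
    return air_density_ideal(EnvironmentalConditions(22.0, 101.325)) * 1e-3
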