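import numpy as np
import pytest
from hypothesis import settings

from ionfep import (
    CouplingState,
    CutoffScheme,
    DielectricMedium,
    generate_water_box,
    load_ion,
    load_water_model,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def water_model():
    return load_water_model()


@pytest.fixture(scope="session")
def medium_1atm():
    return DielectricMedium(eps_r=78.4, pressure=1.0)


@pytest.fixture(scope="session")
def potassium():
    return load_ion("K")


@pytest.fixture(scope="session")
def bromide():
    return load_ion("Br")


@pytest.fixture()
def small_box():
    """16 waters at liquid density; box too small for production cutoffs."""
    return generate_water_box(16, seed=42)


@pytest.fixture()
def small_cutoffs(small_box):
    half = small_box.box_length / 2
    return CutoffScheme(r_iw=0.98 * half, r_ww=0.98 * half)


@pytest.fixture(scope="session")
def full_coupling():
    return CouplingState(lambda_lj=1.0, lambda_q=1.0)
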