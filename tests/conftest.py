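import pytest

from adhesurf import (
    FORMAMIDE,
    METHYLENE_IODIDE,
    WATER,
    ContactAngleMeasurement,
    solve_components,
)

# printed sessile-drop angles for PET: water, formamide, methylene iodide
PET_ANGLES = ((WATER, 77.8, 1.3), (FORMAMIDE, 58.2, 1.8), (METHYLENE_IODIDE, 20.5, 2.2))


@pytest.fixture
def table1_liquids():
    return [WATER, FORMAMIDE, METHYLENE_IODIDE]


@pytest.fixture
def pet_angles():
    return [ContactAngleMeasurement(liq, th, sd) for liq, th, sd in PET_ANGLES]


@pytest.fixture
def pet_components(pet_angles):
    return solve_components(pet_angles, surface_name="PET")
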