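import pytest

from ckdiet import (
    adequacy_grid,
    load_default_db,
    load_default_references,
    load_diet_profiles,
    resolve_references,
)

PRESCRIPTIONS = (0.5, 0.6, 0.7, 0.8, 1.0, 1.1, 1.2)
LPD = (0.5, 0.6, 0.7, 0.8)
MHPD = (1.0, 1.1, 1.2)


@pytest.fixture(scope="session")
def fixture_db():
    """Packaged protein foods plus synthetic menu foods."""
    return load_default_db()


@pytest.fixture(scope="session")
def refs70():
    """Default references resolved for a 70-kg adult at 2100 kcal."""
    return resolve_references(load_default_references(), body_weight=70, energy=2100)


@pytest.fixture(scope="session")
def printed_profiles():
    """The packaged modeled-diet nutrient profiles (6 models x 7 prescriptions)."""
    return load_diet_profiles()


@pytest.fixture(scope="session")
def printed_grid(printed_profiles, refs70):
    return adequacy_grid(printed_profiles, refs70)
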