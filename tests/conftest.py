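import numpy as np
import pytest
from hypothesis import settings

from tracermet.chem_core import IsotopeTable, example_fragment_library

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_isotopes():
    return IsotopeTable.default()


@pytest.fixture(scope="session")
def carbon_only_table():
    """Toy table with only carbon isotopes, matching the hand-derived oracles."""
    return IsotopeTable({"C": ((0, 0.9893), (1, 0.0107))})


@pytest.fixture(scope="session")
def pure_light_table():
    """Degenerate table: every element is 100% its lightest isotope."""
    return IsotopeTable(
        {
            el: ((0, 1.0),)
            for el in ("C", "H", "N", "O", "Si", "S")
        }
    )


@pytest.fixture(scope="session")
def fragment_library():
    return example_fragment_library()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
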