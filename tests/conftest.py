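"""Shared fixtures for the test suite."""

import numpy as np
import pytest

from oligoms.constants import ABETA40_SEQUENCE, ABETA42_SEQUENCE
from oligoms.ion_grid import PeptideSpecies


@pytest.fixture(scope="session")
def abeta40() -> PeptideSpecies:
    return PeptideSpecies.from_sequence("Abeta40", ABETA40_SEQUENCE)


@pytest.fixture(scope="session")
def abeta42() -> PeptideSpecies:
    return PeptideSpecies.from_sequence("Abeta42", ABETA42_SEQUENCE)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
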