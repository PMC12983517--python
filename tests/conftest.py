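from pathlib import Path

import pytest

from vpdx.model import read_case, read_scorecard

FIXTURES = Path(__file__).parent / "fixtures"


@pytest.fixture(scope="session")
def toy_case():
    return read_case(FIXTURES / "toy_mi.case.json")


@pytest.fixture(scope="session")
def toy_scorecard():
    return read_scorecard(FIXTURES / "toy_mi.scorecard.json")
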