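from pathlib import Path

import pandas as pd
import pytest

from beescreen import build_intake_table, load_fixture_panel

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def fixture_panel():
    return load_fixture_panel()


@pytest.fixture(scope="session")
def intake_table(fixture_panel):
    return build_intake_table(fixture_panel)


@pytest.fixture(scope="session")
def printed_intakes():
    """The survey's published weekly-intake table (display units)."""
    return pd.read_csv(DATA / "weekly_intake_printed.csv", index_col=0)


@pytest.fixture(scope="session")
def printed_scores():
    """The survey's published six criterion score columns."""
    return pd.read_csv(DATA / "criterion_scores_printed.csv", index_col=0)
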