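import numpy as np
import pandas as pd
import pytest

from calfclim.simulate import make_fixture
from calfclim.surveys import SurveyTable


@pytest.fixture(scope="session")
def table1_fixture():
    return make_fixture("table1_design_trend", seed=1)


@pytest.fixture(scope="session")
def tiny_toy_fixture():
    return make_fixture("tiny_toy", seed=2)


def make_survey_table(rows) -> SurveyTable:
    """Rows of (subregion, year, season, total, calves)."""
    return SurveyTable(pd.DataFrame(
        rows, columns=["subregion", "year", "season", "total", "calves"]
    ))


@pytest.fixture
def small_table():
    return make_survey_table([
        ("torres_strait", 1991, "spring_summer", 100, 10),
        ("torres_strait", 1996, "spring_summer", 150, 12),
        ("hervey_bay", 1992, "spring_summer", 200, 44),
        ("hervey_bay", 2001, "autumn", 120, 9),
        ("hervey_bay", 2001, "spring_summer", 130, 11),
    ])
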