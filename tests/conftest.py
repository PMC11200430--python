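import pandas as pd
import pytest

from extractopt.design import TABLE1_FACTORS
from extractopt.synthetic import RESPONSE_NAMES, load_table1_fixture


@pytest.fixture(scope="session")
def table1():
    """(design, observed, rsm_predicted, ann_predicted) of the 27-run study."""
    return load_table1_fixture()


@pytest.fixture(scope="session")
def observed_responses(table1) -> pd.DataFrame:
    _, observed, _, _ = table1
    return observed[list(RESPONSE_NAMES)]


@pytest.fixture(scope="session")
def factors():
    return TABLE1_FACTORS
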