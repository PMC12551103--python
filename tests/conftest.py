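import pytest

from cfnbs.cutoffs import CutoffModel
from cfnbs.fixtures import fixture_panel, make_table1_fixture
from cfnbs.screening import classify_cohort


@pytest.fixture(scope="session")
def table1():
    """The deterministic 390-record CF cohort registry."""
    return make_table1_fixture()


@pytest.fixture(scope="session")
def core_panel():
    return fixture_panel("core")


@pytest.fixture(scope="session")
def all_panels():
    return [fixture_panel(n) for n in ("core", "expanded139", "expanded689", "ngs1085")]


@pytest.fixture(scope="session")
def classified(table1, core_panel):
    """Table-1 registry screened at the fixed 55 ng/mL rule and classified."""
    return classify_cohort(table1, core_panel, CutoffModel(mode="fixed", fixed_value=55.0))
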