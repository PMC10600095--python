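import pytest

from circwood import (
    DecarbSchedule,
    ScenarioConfig,
    make_calibrated_fixture,
    run_all_scenarios,
)

SCENARIO_ORDER = ["cascading_circular", "circular", "cascading", "bau"]


@pytest.fixture(scope="session")
def bundle():
    """The calibrated deterministic input bundle (9.5 Mt harvest)."""
    return make_calibrated_fixture()


@pytest.fixture(scope="session")
def results(bundle):
    """All four scenario runs, implementation in study year 5 (2027)."""
    return run_all_scenarios(bundle, ScenarioConfig(scenario_id="bau"))


@pytest.fixture()
def simple_schedule():
    return DecarbSchedule({"any": {2030: 0.6, 2040: 0.3, 2050: 0.0}})
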