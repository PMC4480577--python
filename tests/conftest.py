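import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from gaspbpk.core import DosingSchedule, simulate
from gaspbpk.parameters import build_subject, load_gas, load_species


@pytest.fixture(scope="session")
def human_xe_subject():
    return build_subject(load_species("human"), load_gas("xenon"))


@pytest.fixture(scope="session")
def human_xe_result(human_xe_subject):
    """Reference run: 60 min at 50 % xenon, human, default solver."""
    schedule = DosingSchedule.single("xenon", 50.0, 60.0)
    return simulate(human_xe_subject, schedule)


@pytest.fixture(scope="session")
def chronic_result(human_xe_subject):
    """Ten daily 60-min 50 % xenon episodes in the human model."""
    schedule = DosingSchedule.repeated(
        "xenon", 50.0, 60.0, period_min=1440.0, count=10
    )
    return simulate(human_xe_subject, schedule)


@pytest.fixture(scope="session")
def reference_summaries():
    """PK summaries for the four published scenarios, administration-window
    AUC convention."""
    from gaspbpk.reporting import REFERENCE_SCENARIOS, run_scenario

    out = {}
    for gas, species in REFERENCE_SCENARIOS:
        _, summary = run_scenario(gas, species)
        out[(gas, species)] = summary
    return out
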