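import pytest

from crossgaze.detection import DetectorConfig
from crossgaze.scenario import make_default_scenario
from crossgaze.synthetic import BehaviourParams, Participant


@pytest.fixture(scope="session")
def scenario():
    return make_default_scenario()


@pytest.fixture(scope="session")
def params():
    return BehaviourParams.default()


@pytest.fixture(scope="session")
def detector_cfg():
    return DetectorConfig()


@pytest.fixture(scope="session")
def control_participant():
    return Participant(participant_id="co01", group="control", age=50,
                       moca=22, va_decimal=1.0, vf_radius=85)
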