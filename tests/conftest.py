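import hypothesis
import pytest

from rtrepp import LinkScorer, ReppConfig, SimulationConfig

hypothesis.settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=50
)
hypothesis.settings.load_profile("ci")


@pytest.fixture
def scorer() -> LinkScorer:
    return LinkScorer.default()


@pytest.fixture
def repp_cfg() -> ReppConfig:
    return ReppConfig()


@pytest.fixture
def sim_cfg() -> SimulationConfig:
    return SimulationConfig()
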