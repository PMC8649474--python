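import pytest
from hypothesis import HealthCheck, settings

from smartalloc import ObjectiveWeights, ResponseRates

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


#: The three weight sets of the worked weight-loss example, text ordering
#: (l13, l14, l23, l24).
WEIGHT_SETS = {
    "equal": ObjectiveWeights(0.25, 0.25, 0.25, 0.25),
    "single_emphasis": ObjectiveWeights(0.70, 0.10, 0.10, 0.10),
    "combined_emphasis": ObjectiveWeights(0.10, 0.10, 0.10, 0.70),
}

#: The three response-rate guesses of the worked example.
RATE_SETS = [
    ResponseRates(0.15, 0.25),
    ResponseRates(0.25, 0.40),
    ResponseRates(0.40, 0.55),
]


@pytest.fixture
def equal_weights():
    return WEIGHT_SETS["equal"]


@pytest.fixture
def single_emphasis_weights():
    return WEIGHT_SETS["single_emphasis"]


@pytest.fixture
def combined_emphasis_weights():
    return WEIGHT_SETS["combined_emphasis"]


@pytest.fixture
def low_rates():
    return RATE_SETS[0]


@pytest.fixture
def mid_rates():
    return RATE_SETS[1]
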