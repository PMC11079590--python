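import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

from protmr.simulate import ScenarioConfig, simulate_mediation_scenario  # noqa: E402
from protmr.sumstats import HarmonizedPairs  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(20240425)


@pytest.fixture
def concordant_pairs(rng):
    """10 instruments, one true causal slope, no pleiotropy."""
    k = 10
    x = rng.uniform(0.05, 0.15, k)
    sx = np.full(k, 0.002)
    sy = np.full(k, 0.01)
    xo = rng.normal(x, sx)
    yo = rng.normal(0.3 * x, sy)
    return HarmonizedPairs.from_arrays(xo, sx, yo, sy)


@pytest.fixture(scope="session")
def small_scenario():
    """Default-condition scenario shrunk to a 20-protein panel for speed."""
    return simulate_mediation_scenario(ScenarioConfig(panel_size=20, seed=11))
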