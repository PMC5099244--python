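import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from haploselect import HaplotypeDistribution, HazardSet, Scenario, load_preset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(params=["A", "B", "C", "D"])
def preset(request):
    return load_preset(request.param)


def random_scenarios(n, seed, horizon=60.0):
    """Random valid scenarios: Dirichlet frequencies, log-uniform hazards."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        freqs = rng.dirichlet(np.ones(4))
        freqs = freqs / freqs.sum()
        rates = np.exp(rng.uniform(np.log(0.005), np.log(0.3), size=4))
        out.append(
            Scenario(
                label=f"rand{i}",
                dist0=HaplotypeDistribution(*freqs),
                hazards=HazardSet(*rates),
                horizon=horizon,
            )
        )
    return out
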