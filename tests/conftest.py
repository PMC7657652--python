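import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

from circinventory import consensus, simdata  # noqa: E402


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic study at the default design: 3 stages x 2 treatments,
    300 true circles + 150 artifacts, seed 17."""
    cfg = simdata.SimConfig(seed=17)
    truth, libs = simdata.simulate_dataset(cfg)
    return cfg, truth, libs


@pytest.fixture(scope="session")
def default_inventory(default_dataset):
    _, truth, libs = default_dataset
    calls = [c for tool_calls in libs.calls.values() for c in tool_calls]
    records, summary = consensus.build_inventory(calls, libs.metas)
    return records, summary
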