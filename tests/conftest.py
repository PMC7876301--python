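import pytest
from hypothesis import HealthCheck, settings

import cvrlag as cl

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def block_trace() -> cl.EndTidalTrace:
    return cl.make_trace(cl.block_hc())


@pytest.fixture(scope="session")
def small_noiseless_phantom(block_trace):
    """12x12x2 noiseless block phantom with its ground truth."""
    spec = cl.PhantomSpec(grid_shape=(12, 12, 2), tsnr=0.0, seed=0)
    bold, truth, trace = cl.simulate_bold(block_trace, spec)
    return bold, truth, trace, spec
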