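import pytest

from trialvalue import RunConfig, generate_blocks, solve_boundary
from trialvalue.synthetic_data import profher_like_spec


@pytest.fixture(scope="session")
def config250():
    """Shipped application defaults (q_max = 250)."""
    return RunConfig()


@pytest.fixture(scope="session")
def config125():
    return RunConfig(q_max=125)


@pytest.fixture(scope="session")
def boundary250(config250):
    return solve_boundary(config250.params(), config250.prior(), config250.grid())


@pytest.fixture(scope="session")
def boundary125(config125):
    return solve_boundary(config125.params(), config125.prior(), config125.grid())


@pytest.fixture(scope="session")
def synth_blocks():
    """Synthetic stand-in for the application's block-level summaries."""
    return generate_blocks(profher_like_spec(seed=1, n_pairs=250))
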