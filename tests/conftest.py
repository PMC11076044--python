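import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gravistoch.physics import SimConfig
from gravistoch.stacks import Block, Stack, StackGenConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fast_sim():
    """Short simulation horizon for unit tests."""
    return SimConfig(n_stages=120)


def make_stack(blocks, n_blocks=None):
    cfg = StackGenConfig(n_blocks=n_blocks or max(len(blocks), 2), seed=0)
    return Stack(blocks=list(blocks), gen_config=cfg)


@pytest.fixture(scope="session")
def single_block_stack():
    # a lone block resting flat on the ground (padded config for the 2-block
    # minimum is irrelevant to physics)
    return make_stack([Block("long-x", [0.0, 0.0, 0.2])], n_blocks=2)


@pytest.fixture(scope="session")
def stable_tower():
    """Two well-overlapped blocks; statically stable."""
    return make_stack(
        [Block("long-x", [0.0, 0.0, 0.2]), Block("long-x", [0.1, 0.0, 0.6])]
    )


@pytest.fixture(scope="session")
def overhang_tower():
    """Top block overhangs far beyond support; topples under natural gravity."""
    return make_stack(
        [Block("long-x", [0.0, 0.0, 0.2]), Block("long-x", [1.14, 0.0, 0.6])]
    )


@pytest.fixture(scope="session")
def crossing_tower():
    """Three mutually crossing blocks (face contacts without vertex inclusion)."""
    return make_stack(
        [
            Block("long-x", [0.0, 0.0, 0.2]),
            Block("long-y", [0.05, 0.0, 0.6]),
            Block("long-z", [0.0, 0.05, 1.4]),
        ]
    )
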